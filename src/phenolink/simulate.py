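"""Forward simulation of the full same-cell study.

Everything downstream of the instrument is testable against this module: it
generates (a) sealed-microwell two-channel sensor kinetics for cells with a
known true OCR, (b) a structured 96-gene log-expression matrix with
non-detect dropout, and (c) repeated hypoxia bottleneck selection with
re-expansion on a population carrying a latent survival trait.

The defaults encode the study conditions the simulated experiment emulates:
four esophageal cell types (a metaplastic CP-A analog and three dysplastic
CP-B/C/D analogs), each with a control and a hypoxia-resistant strain,
20-24 cells per strain, 140 pL sealed wells, a 96-gene panel grouped into
hypoxia-relevant functional categories, zero-inflated lognormal OCR with
18-35% non-respirers in every strain except the control CP-A analog, and
six 10%-survival hypoxia bottlenecks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataError
from .ocr import K_U, CalibrationModel, SensorTrace, WellGeometry

CONTROL = "control"
HYPOXIA = "hypoxia"

# -- gene panel ---------------------------------------------------------------
# 96 genes in the functional categories relevant to hypoxia response;
# housekeeping genes are carried separately and get near-zero dropout.
GENE_PANEL: dict[str, tuple[str, ...]] = {
    "housekeeping": ("GAPDH", "ACTB", "B2M", "HPRT1", "GUSB", "TBP"),
    "glycolysis/glucose metabolism": (
        "SLC2A1", "SLC2A3", "HK1", "HK2", "GPI", "PFKL", "PFKM", "ALDOA",
        "TPI1", "PGK1", "PGAM1", "ENO1", "ENO2", "PKM", "LDHA", "LDHB", "PDK1",
    ),
    "blood vessel development/morphogenesis": (
        "VEGFA", "VEGFC", "FLT1", "KDR", "ANGPT1", "ANGPT2", "TEK", "FGF2",
        "PDGFB", "EPO", "EPAS1", "HIF1A", "ARNT", "SERPINE1", "TGFB1",
    ),
    "positive regulation of chemotaxis": (
        "CXCL8", "CXCL12", "CXCR4", "CCL2", "IL6", "PDGFA", "HGF", "MET",
        "EDN1", "S100A4",
    ),
    "cell migration/motility": (
        "MMP2", "MMP9", "TIMP1", "ITGA5", "ITGB1", "CDH1", "CDH2", "VIM",
        "SNAI1", "SNAI2", "TWIST1", "FN1", "RHOA", "RAC1",
    ),
    "phosphorylation and phosphorus metabolic process": (
        "AKT1", "PIK3CA", "MTOR", "MAPK1", "MAPK3", "MAP2K1", "EGFR", "ERBB2",
        "SRC", "JAK2", "STAT3", "PRKAA1", "PRKCA",
    ),
    "phosphorylation regulation": (
        "PTEN", "DUSP1", "PPP2CA", "CDKN1A", "CDKN1B", "CDKN2A", "CCND1",
        "CDK4", "TP53", "RB1",
    ),
    "regulation of apoptosis": (
        "BAX", "BCL2", "BAK1", "BID", "CASP3", "CASP8", "CASP9", "BNIP3",
        "BNIP3L", "TNF", "FAS",
    ),
}


def panel_genes() -> list[str]:
    """The default 96-gene panel, in fixed category order."""
    return [g for genes in GENE_PANEL.values() for g in genes]


def panel_categories() -> dict[str, str]:
    """Map gene symbol -> functional category label."""
    return {g: cat for cat, genes in GENE_PANEL.items() for g in genes}


# -- domain types -------------------------------------------------------------


@dataclass(frozen=True)
class SensorModel:
    """Photophysics of the ratiometric sensor pair.

    Ideal Stern-Volmer quenching of the sensor/reference ratio:
    ``rho(C) = i0 / (1 + ksv * C)``.  ``noise_sd`` is multiplicative
    per-sample intensity noise on each channel independently;
    ``drift_per_min`` is a linear drift on the reference channel only (it
    does *not* cancel in the ratio and exists to test that).
    """

    ksv: float = 0.005
    i0: float = 2.0
    ref_level: float = 1000.0
    noise_sd: float = 0.0
    drift_per_min: float = 0.0

    def __post_init__(self) -> None:
        if not self.ksv > 0:
            raise ConfigurationError(f"ksv must be positive, got {self.ksv}")
        if not self.i0 > 0:
            raise ConfigurationError(f"i0 must be positive, got {self.i0}")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")

    def calibration(self) -> CalibrationModel:
        """The exact CalibrationModel matching this forward model."""
        return CalibrationModel(ksv=self.ksv, i0=self.i0, provenance="configured")


@dataclass(frozen=True)
class OCRPopulationModel:
    """Zero-inflated lognormal model of single-cell OCR within one strain.

    A cell is a non-respirer (OCR = 0) with probability
    ``nonrespirer_fraction``; otherwise its OCR is lognormal with the given
    log-scale location and shape.  Values below ``detection_floor`` are
    recorded as zero, mirroring how the instrument reports them.
    """

    nonrespirer_fraction: float = 0.25
    log_mean: float = float(np.log(1.5))
    log_sd: float = 0.5
    detection_floor: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.nonrespirer_fraction <= 1.0:
            raise ConfigurationError(
                f"nonrespirer_fraction must be in [0, 1], got {self.nonrespirer_fraction}"
            )
        if self.detection_floor < 0:
            raise ConfigurationError(
                f"detection_floor must be >= 0, got {self.detection_floor}"
            )


@dataclass
class ExpressionDesign:
    """Generative design of the genes x cells log-expression matrix.

    Each latent cluster has a centroid vector of mean log-expression; a
    cell's profile is its cluster centroid plus iid Gaussian noise, and each
    gene independently drops out (non-detect) with a per-gene probability.
    Housekeeping genes use ``housekeeping_dropout`` instead.
    """

    genes: list[str]
    gene_categories: dict[str, str]
    cluster_centroids: dict[str, np.ndarray]
    within_cluster_sd: float = 1.0
    dropout_prob_per_gene: dict[str, float] | float = 0.15
    housekeeping_genes: tuple[str, ...] = GENE_PANEL["housekeeping"]
    housekeeping_dropout: float = 0.005

    def __post_init__(self) -> None:
        n = len(self.genes)
        for label, c in self.cluster_centroids.items():
            self.cluster_centroids[label] = np.asarray(c, dtype=float)
            if len(self.cluster_centroids[label]) != n:
                raise ConfigurationError(
                    f"centroid {label!r} has {len(c)} entries, expected {n}"
                )
        missing = set(self.housekeeping_genes) - set(self.genes)
        if missing:
            raise ConfigurationError(f"housekeeping genes not in panel: {sorted(missing)}")
        for p in self.dropout_vector():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"dropout probability {p} outside [0, 1]")

    def dropout_vector(self) -> np.ndarray:
        if isinstance(self.dropout_prob_per_gene, dict):
            probs = np.array(
                [self.dropout_prob_per_gene.get(g, 0.0) for g in self.genes], dtype=float
            )
        else:
            probs = np.full(len(self.genes), float(self.dropout_prob_per_gene))
        hk = np.isin(self.genes, self.housekeeping_genes)
        probs[hk] = self.housekeeping_dropout
        return probs


@dataclass(frozen=True)
class SelectionConfig:
    """Repeated hypoxia bottleneck selection with re-expansion.

    ``heritability`` couples a latent survival trait to who survives each
    bottleneck (1 = strict trait-rank selection and faithful inheritance,
    0 = uniform survival and full regression to the survivor mean).
    """

    n_rounds: int = 6
    survival_fraction: float = 0.10
    heritability: float = 0.0
    expansion_size: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.survival_fraction <= 1.0:
            raise ConfigurationError(
                f"survival_fraction must be in (0, 1], got {self.survival_fraction}"
            )
        if not 0.0 <= self.heritability <= 1.0:
            raise ConfigurationError(
                f"heritability must be in [0, 1], got {self.heritability}"
            )
        if self.n_rounds < 0:
            raise ConfigurationError(f"n_rounds must be >= 0, got {self.n_rounds}")


# columns of a study manifest DataFrame
MANIFEST_COLUMNS = ("cell_id", "cell_type", "strain", "true_ocr", "latent_cluster")


@dataclass
class StudyConfig:
    """Top-level configuration for :func:`generate_study`."""

    cell_types: tuple[str, ...] = ("CP-A", "CP-B", "CP-C", "CP-D")
    cells_per_strain: tuple[int, int] = (20, 24)
    # per-strain non-respirer fractions; key "<c|h><cell type>"
    nonrespirer_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "cCP-A": 0.0, "hCP-A": 0.22,
            "cCP-B": 0.25, "hCP-B": 0.30,
            "cCP-C": 0.18, "hCP-C": 0.20,
            "cCP-D": 0.28, "hCP-D": 0.35,
        }
    )
    log_mean: float = float(np.log(1.5))
    log_sd: float = 0.5
    detection_floor: float = 0.1
    geometry: WellGeometry = field(default_factory=WellGeometry)
    sensor: SensorModel = field(default_factory=lambda: SensorModel(noise_sd=0.01))
    trace_duration_min: float = 40.0
    trace_dt_min: float = 1.0
    # expression design knobs
    n_genes: int = 96
    between_cluster_sd: float = 1.2
    within_cluster_sd: float = 1.0
    baseline_log_expression: float = 5.0
    dropout_prob: float = 0.15
    # CP-B and CP-D analogs split into two latent sub-clusters each
    bimodal_types: tuple[str, ...] = ("CP-B", "CP-D")


def group_label(cell_type: str, strain: str) -> str:
    """Strain group label in the 'cCP-A' / 'hCP-A' style."""
    return ("c" if strain == CONTROL else "h") + cell_type


# -- operations ---------------------------------------------------------------


def simulate_ocr_population(model: OCRPopulationModel, n: int, seed) -> np.ndarray:
    """Draw ``n`` true single-cell OCR values (fmol/min) from the mixture."""
    if n < 1:
        raise ConfigurationError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    zero = rng.random(n) < model.nonrespirer_fraction
    vals = rng.lognormal(mean=model.log_mean, sigma=model.log_sd, size=n)
    vals[zero] = 0.0
    vals[vals < model.detection_floor] = 0.0
    return vals


def simulate_sensor_trace(
    true_ocr: float,
    geom: WellGeometry,
    sensor: SensorModel,
    duration: float,
    dt: float,
    seed,
    *,
    cell_id: str = "sim",
    leak_per_min: float = 0.0,
    external_o2_um: float | None = None,
) -> SensorTrace:
    """Simulate one sealed-well drawdown as a two-channel intensity trace.

    Oxygen amount follows ``A(t) = max(0, V*C0*K_U - OCR*t)`` (clamped at
    the depletion floor); with ``leak_per_min > 0`` an exchange term pulls
    the interior toward ``external_o2_um`` (Euler steps), which is how seal
    failures and purge-based QC tests are emulated.  The emitted channels
    carry multiplicative noise, and the reference channel alone carries the
    configured linear drift.
    """
    if duration <= 0 or dt <= 0:
        raise ConfigurationError("duration and dt must be positive")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration + dt / 2, dt)
    a0 = geom.total_o2_fmol
    if leak_per_min == 0.0:
        amount = np.maximum(0.0, a0 - true_ocr * times)
    else:
        ext = geom.initial_o2_um if external_o2_um is None else external_o2_um
        a_ext = geom.volume_pl * ext * K_U
        amount = np.empty_like(times)
        amount[0] = a0
        for i in range(1, len(times)):
            da = -true_ocr + leak_per_min * (a_ext - amount[i - 1])
            amount[i] = max(0.0, amount[i - 1] + da * dt)
    conc = amount / (geom.volume_pl * K_U)
    rho = sensor.i0 / (1.0 + sensor.ksv * conc)

    drift = 1.0 + sensor.drift_per_min * times
    if sensor.noise_sd > 0:
        noise_ref = np.clip(1.0 + sensor.noise_sd * rng.standard_normal(len(times)), 0.01, None)
        noise_sen = np.clip(1.0 + sensor.noise_sd * rng.standard_normal(len(times)), 0.01, None)
    else:
        noise_ref = noise_sen = 1.0
    reference = sensor.ref_level * drift * noise_ref
    signal = rho * sensor.ref_level * noise_sen
    return SensorTrace(
        cell_id=cell_id, times=times, sensor=signal, reference=reference, well=geom
    )


def simulate_expression_matrix(
    design: ExpressionDesign, manifest: pd.DataFrame, seed
) -> pd.DataFrame:
    """Genes x cells log-expression matrix; non-detects are NaN.

    Each cell's profile is its latent-cluster centroid plus iid Gaussian
    noise; dropout is Bernoulli per gene per cell.
    """
    rng = np.random.default_rng(seed)
    genes = design.genes
    dropout = design.dropout_vector()
    cols = {}
    for _, row in manifest.iterrows():
        label = str(row["latent_cluster"])
        if label not in design.cluster_centroids:
            raise ConfigurationError(
                f"cell {row['cell_id']!r}: no centroid for latent cluster {label!r}"
            )
        values = design.cluster_centroids[label] + design.within_cluster_sd * rng.standard_normal(
            len(genes)
        )
        drop = rng.random(len(genes)) < dropout
        values = values.astype(float)
        values[drop] = np.nan
        cols[row["cell_id"]] = values
    return pd.DataFrame(cols, index=pd.Index(genes, name="gene"))


def _as_population(base_population) -> pd.DataFrame:
    if isinstance(base_population, pd.DataFrame):
        if "trait" not in base_population.columns:
            raise DataError("population DataFrame must have a 'trait' column")
        return base_population.reset_index(drop=True).copy()
    arr = np.asarray(base_population, dtype=float)
    if arr.ndim != 1:
        raise DataError("population array must be one-dimensional")
    return pd.DataFrame({"trait": arr})


def simulate_hypoxia_selection(base_population, cfg: SelectionConfig, seed) -> pd.DataFrame:
    """Repeated bottleneck selection on a latent survival trait.

    Each round keeps ``round(N * survival_fraction)`` cells: a fraction
    ``heritability`` of the survivor slots go to the top-ranked traits, the
    rest are drawn uniformly from the remainder.  Survivors are re-expanded
    to ``expansion_size`` by resampling with replacement; offspring inherit
    the parent's phenotype columns while the trait regresses between the
    survivor mean and the base (environmental) distribution::

        trait' = h*m_surv + (1-h)*m_base + h*(parent - m_surv)
                 + sqrt(1 - h^2) * s_base * eps

    so ``h = 1`` copies the parent trait faithfully and ``h = 0`` redraws a
    non-heritable trait from the stable base distribution each generation
    (no drift, matching a trait with purely environmental variance).

    ``base_population`` may be a 1-D trait array or a DataFrame with a
    ``trait`` column plus arbitrary phenotype columns (carried through).
    """
    pop = _as_population(base_population)
    expansion = cfg.expansion_size if cfg.expansion_size is not None else len(pop)
    if len(pop) * cfg.survival_fraction < 1:
        raise DataError(
            f"population of {len(pop)} cannot yield a survivor at "
            f"survival_fraction={cfg.survival_fraction}"
        )
    rng = np.random.default_rng(seed)
    h = cfg.heritability
    base_traits = pop["trait"].to_numpy()
    m_base = float(base_traits.mean())
    s_base = float(base_traits.std(ddof=1)) if len(base_traits) > 1 else 0.0
    for _ in range(cfg.n_rounds):
        n = len(pop)
        n_surv = int(round(n * cfg.survival_fraction))
        if n_surv < 1:
            raise DataError("empty survivor set")
        traits = pop["trait"].to_numpy()
        order = np.argsort(-traits, kind="stable")
        k_rank = int(round(h * n_surv))
        ranked = order[:k_rank]
        pool = order[k_rank:]
        random_pick = rng.choice(pool, size=n_surv - k_rank, replace=False)
        surv = pop.iloc[np.concatenate([ranked, random_pick])].reset_index(drop=True)

        s_traits = surv["trait"].to_numpy()
        m_surv = float(s_traits.mean())
        parents = rng.integers(0, len(surv), size=expansion)
        children = surv.iloc[parents].reset_index(drop=True)
        eps = rng.standard_normal(expansion)
        center = h * m_surv + (1.0 - h) * m_base
        children["trait"] = (
            center
            + h * (s_traits[parents] - m_surv)
            + np.sqrt(max(0.0, 1.0 - h * h)) * s_base * eps
        )
        pop = children
    return pop


def _build_manifest(config: StudyConfig, rng: np.random.Generator) -> pd.DataFrame:
    lo, hi = config.cells_per_strain
    rows = []
    for cell_type in config.cell_types:
        bimodal = cell_type in config.bimodal_types
        for strain in (CONTROL, HYPOXIA):
            grp = group_label(cell_type, strain)
            n_cells = int(rng.integers(lo, hi + 1))
            frac = config.nonrespirer_fractions.get(grp, 0.25)
            ocr_model = OCRPopulationModel(
                nonrespirer_fraction=frac,
                log_mean=config.log_mean,
                log_sd=config.log_sd,
                detection_floor=config.detection_floor,
            )
            ocrs = simulate_ocr_population(ocr_model, n_cells, rng)
            for j in range(n_cells):
                if bimodal:
                    cluster = f"{cell_type}.{1 + int(rng.random() < 0.5)}"
                else:
                    cluster = f"{cell_type}.1"
                rows.append(
                    {
                        "cell_id": f"{grp}_{j + 1:03d}",
                        "cell_type": cell_type,
                        "strain": strain,
                        "true_ocr": float(ocrs[j]),
                        "latent_cluster": cluster,
                    }
                )
    return pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))


def default_expression_design(config: StudyConfig, rng: np.random.Generator) -> ExpressionDesign:
    """Expression design with one centroid per latent cluster.

    Centroids are drawn once around a common baseline with between-cluster
    spread comparable to the within-cluster noise, producing the "highly
    heterogeneous landscape with only slight clustering by cell type" regime
    rather than cleanly separable blobs.
    """
    genes = panel_genes()[: config.n_genes]
    clusters = []
    for ct in config.cell_types:
        clusters.append(f"{ct}.1")
        if ct in config.bimodal_types:
            clusters.append(f"{ct}.2")
    centroids = {
        label: config.baseline_log_expression
        + config.between_cluster_sd * rng.standard_normal(len(genes))
        for label in clusters
    }
    return ExpressionDesign(
        genes=genes,
        gene_categories={g: panel_categories()[g] for g in genes},
        cluster_centroids=centroids,
        within_cluster_sd=config.within_cluster_sd,
        dropout_prob_per_gene=config.dropout_prob,
    )


def generate_study(
    config: StudyConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
):
    """Simulate a full study: manifest, per-well traces, expression matrix.

    Deterministic given ``seed``.  If ``out_dir`` is given, writes
    ``manifest.json``, ``expression.tsv`` and one ``traces/<cell_id>.tsv``
    per well (delimited text only) and records the trace file names in the
    manifest.

    Returns
    -------
    (manifest, traces, expression) :
        manifest DataFrame, dict cell_id -> SensorTrace, genes x cells
        DataFrame with NaN non-detects.
    """
    from . import io as _io

    config = config or StudyConfig()
    rng = np.random.default_rng(seed)
    manifest = _build_manifest(config, rng)
    design = default_expression_design(config, rng)
    expression = simulate_expression_matrix(
        design, manifest, rng.integers(0, 2**31 - 1)
    )
    traces = {}
    for _, row in manifest.iterrows():
        traces[row["cell_id"]] = simulate_sensor_trace(
            row["true_ocr"],
            config.geometry,
            config.sensor,
            duration=config.trace_duration_min,
            dt=config.trace_dt_min,
            seed=rng.integers(0, 2**31 - 1),
            cell_id=row["cell_id"],
        )

    if out_dir is not None:
        out = Path(out_dir)
        (out / "traces").mkdir(parents=True, exist_ok=True)
        manifest = manifest.copy()
        manifest["well_file"] = [f"traces/{cid}.tsv" for cid in manifest["cell_id"]]
        for cid, trace in traces.items():
            _io.write_trace(trace, out / "traces" / f"{cid}.tsv")
        _io.write_manifest(manifest, out / "manifest.json")
        _io.write_expression_matrix(expression, out / "expression.tsv")
    return manifest, traces, expression
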