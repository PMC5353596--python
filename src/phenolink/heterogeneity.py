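"""Expression normalization, pooled clustering and the TES/RV statistics.

The heterogeneity question: after repeated hypoxia bottlenecks, does a
strain's transcriptional diversity shrink or grow relative to its control?
All analyzed cells are pooled and hierarchically clustered into ``k``
clusters; cluster ``i`` holds a fraction ``p_i = N_i / N_total`` of the
pool.  For a strain group ``g`` with occupancy fractions ``f_{g,i}`` the
per-cluster enrichment ratio is ``ES_{g,i} = f_{g,i} / p_i`` (observed over
chance), and the Total Enrichment Score aggregates it weighted by occupancy:

    TES_g = sum_i f_{g,i} * ES_{g,i} = sum_i f_{g,i}^2 / p_i

TES is 1 exactly when the group is spread like the pool (maximal diversity)
and N_total/n_g when it fully owns one cluster (minimal diversity); higher
TES means lower variability.  The Relative Variability of a control/
hypoxia-resistant strain pair is RV = TES_control / TES_hypoxia, so RV < 1
means selection reduced transcriptional variability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .exceptions import ConfigurationError, DataError

logger = logging.getLogger(__name__)

MIN_DETECTED_CELLS = 3


@dataclass
class NormalizedMatrix:
    """Z-scored genes x cells matrix with non-detect bookkeeping.

    ``values`` carries Z scores for every retained gene/cell (imputed
    entries included); ``detected`` marks originally observed entries and
    ``imputed`` their complement; genes observed in fewer than three cells
    are dropped and listed in ``dropped_genes``.
    """

    values: pd.DataFrame
    detected: pd.DataFrame
    imputed: pd.DataFrame
    dropped_genes: list[str]
    metadata: dict = field(default_factory=dict)

    @property
    def cells(self) -> pd.Index:
        return self.values.columns

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def cells_by_genes(self) -> pd.DataFrame:
        """Transposed view (cells as rows) for clustering/embedding."""
        return self.values.T


@dataclass
class ClusterAssignment:
    """Pooled clustering labels with per-cluster occupancy.

    ``labels`` maps cell id -> cluster index in 1..k; ``occupancy`` holds
    N_i and ``p`` the fractions p_i = N_i / N_total.
    """

    labels: pd.Series
    k: int
    linkage_method: str
    distance_metric: str
    occupancy: pd.Series
    p: pd.Series
    linkage_matrix: np.ndarray | None = None

    @property
    def n_total(self) -> int:
        return int(self.occupancy.sum())

    def to_newick(self) -> str:
        """Newick export of the merge tree (leaf names = cell ids)."""
        if self.linkage_matrix is None:
            raise DataError("no linkage matrix stored")
        tree = hierarchy.to_tree(self.linkage_matrix)
        names = list(self.labels.index)

        def rec(node):
            if node.is_leaf():
                return names[node.id]
            return f"({rec(node.left)},{rec(node.right)}):{node.dist:.6g}"

        return rec(tree) + ";"


@dataclass
class EnrichmentResult:
    """Per-group occupancy fractions, enrichment ratios and TES values."""

    f: pd.DataFrame  # groups x clusters occupancy fractions
    es: pd.DataFrame  # groups x clusters enrichment ratios f/p
    tes: pd.Series  # per-group total enrichment score
    group_sizes: pd.Series


@dataclass(frozen=True)
class RelativeVariability:
    """RV = TES_control / TES_hypoxia, raw and rounded to 2 decimals."""

    raw: float
    rounded: float

    def __float__(self) -> float:
        return self.raw


def normalize_expression(matrix: pd.DataFrame) -> NormalizedMatrix:
    """Two-step normalization of a genes x cells matrix with non-detects.

    Non-detects (NaN) are imputed at the per-gene minimum detected value and
    flagged; the global mean of all detected entries is subtracted; each
    gene is then Z-scored using the mean and sample SD (ddof=1) of its
    detected entries, so detected entries of every retained gene have mean 0
    and SD 1.  Genes detected in fewer than three cells are dropped.
    """
    if matrix.size == 0:
        raise DataError("empty expression matrix")
    detected = matrix.notna()
    keep = detected.sum(axis=1) >= MIN_DETECTED_CELLS
    dropped = list(matrix.index[~keep])
    if dropped:
        logger.info("dropping %d gene(s) detected in < %d cells: %s",
                    len(dropped), MIN_DETECTED_CELLS, dropped)
    matrix = matrix.loc[keep]
    detected = detected.loc[keep]
    if matrix.size == 0:
        raise DataError("no genes remain after the detection filter")

    gene_min = matrix.min(axis=1)
    imputed = ~detected
    filled = np.where(detected.to_numpy(), matrix.to_numpy(dtype=float),
                      gene_min.to_numpy()[:, None])
    values = pd.DataFrame(filled, index=matrix.index, columns=matrix.columns)

    global_mean = float(matrix.values[detected.values].mean())
    values = values - global_mean

    det_vals = values.where(detected)
    gene_mean = det_vals.mean(axis=1)
    gene_sd = det_vals.std(axis=1, ddof=1)
    constant = gene_sd == 0
    safe_sd = gene_sd.mask(constant, 1.0)
    z = values.sub(gene_mean, axis=0).div(safe_sd, axis=0)
    z.loc[constant, :] = 0.0

    return NormalizedMatrix(
        values=z,
        detected=detected,
        imputed=imputed,
        dropped_genes=dropped,
        metadata={
            "global_mean": global_mean,
            "gene_means": gene_mean.to_dict(),
            "gene_sds": gene_sd.to_dict(),
            "sd_convention": "sample (ddof=1)",
            "imputation": "per-gene minimum detected value",
            "constant_genes": list(matrix.index[constant]),
        },
    )


def _as_cell_matrix(data) -> tuple[np.ndarray, pd.Index]:
    """Coerce input to (cells x features array, cell index)."""
    if isinstance(data, NormalizedMatrix):
        df = data.cells_by_genes()
        return df.to_numpy(dtype=float), df.index
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), data.index
    if isinstance(data, pd.Series):
        return data.to_numpy(dtype=float).reshape(-1, 1), data.index
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 1:
        arr = arr.reshape(-1, 1)
    return arr, pd.RangeIndex(len(arr))


def hierarchical_cluster(
    data, k: int, linkage: str = "ward", metric: str = "euclidean"
) -> ClusterAssignment:
    """Agglomerative clustering of cells cut into exactly ``k`` clusters.

    ``data`` may be a NormalizedMatrix (transposed internally), a cells x
    features DataFrame/array, or a 1-D vector (e.g. OCR values).  The scipy
    merge order is deterministic for a given input order; labels are
    renumbered 1..k in order of first appearance so permuting cells changes
    labels but never the partition.
    """
    x, index = _as_cell_matrix(data)
    n = len(x)
    if k > n:
        raise ConfigurationError(f"k={k} exceeds the number of cells ({n})")
    if np.isnan(x).any():
        raise DataError("clustering input contains missing values; normalize first")
    if k == n:
        raw = np.arange(1, n + 1)
        z = None
    else:
        z = hierarchy.linkage(pdist(x, metric=metric), method=linkage)
        raw = hierarchy.fcluster(z, t=k, criterion="maxclust")
    # renumber in order of first appearance for stable downstream reporting
    remap: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, lab in enumerate(raw):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        labels[i] = remap[lab]
    if len(remap) != k:
        raise DataError(
            f"could not cut the tree into {k} non-empty clusters (got {len(remap)})"
        )
    series = pd.Series(labels, index=index, name="cluster")
    occupancy = series.value_counts().sort_index()
    occupancy.index.name = "cluster"
    p = occupancy / n
    return ClusterAssignment(
        labels=series,
        k=k,
        linkage_method=linkage,
        distance_metric=metric,
        occupancy=occupancy,
        p=p,
        linkage_matrix=z,
    )


def enrichment_scores(assignment: ClusterAssignment, groups: pd.Series) -> EnrichmentResult:
    """Per-group occupancy fractions, enrichment ratios and TES.

    ``groups`` maps cell id -> group label (e.g. 'cCP-A') and must cover
    every clustered cell with every group non-empty.
    """
    groups = groups.reindex(assignment.labels.index)
    if groups.isna().any():
        missing = list(groups.index[groups.isna()])[:3]
        raise DataError(f"cells without a group label, e.g. {missing}")
    clusters = assignment.occupancy.index
    counts = (
        pd.crosstab(groups, assignment.labels)
        .reindex(columns=clusters, fill_value=0)
    )
    sizes = counts.sum(axis=1)
    if (sizes == 0).any():
        raise DataError(f"empty group(s): {list(sizes.index[sizes == 0])}")
    f = counts.div(sizes, axis=0)
    es = f.div(assignment.p, axis=1)
    tes = (f * es).sum(axis=1)
    tes.name = "TES"
    return EnrichmentResult(f=f, es=es, tes=tes, group_sizes=sizes)


def relative_variability(tes_control: float, tes_hypoxia: float) -> RelativeVariability:
    """RV = TES_control / TES_hypoxia; RV < 1 means variability decreased."""
    if tes_control <= 0 or tes_hypoxia <= 0:
        raise DataError(
            f"TES values must be positive, got ({tes_control}, {tes_hypoxia})"
        )
    raw = tes_control / tes_hypoxia
    return RelativeVariability(raw=raw, rounded=round(raw, 2))


def compare_groups(
    ocr_table: pd.DataFrame,
    *,
    value_col: str = "ocr_fmol_min",
    type_col: str = "cell_type",
    strain_col: str = "strain",
    control: str = "control",
    hypoxia: str = "hypoxia",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Control vs hypoxia-resistant OCR comparison per cell type.

    Reports a Welch (unequal-variance) t test on means and a two-sided
    Mann-Whitney rank test, each Benjamini-Hochberg adjusted across cell
    types.  Degenerate pairs (both groups constant and identical) are
    reported with p = 1 and flagged.
    """
    if len(ocr_table) == 0:
        raise DataError("empty OCR table")
    rows = []
    for cell_type, sub in ocr_table.groupby(type_col, sort=True):
        a = sub.loc[sub[strain_col] == control, value_col].to_numpy(dtype=float)
        b = sub.loc[sub[strain_col] == hypoxia, value_col].to_numpy(dtype=float)
        if len(a) < 3 or len(b) < 3:
            raise DataError(
                f"cell type {cell_type!r}: each strain needs >= 3 cells "
                f"(got {len(a)}, {len(b)})"
            )
        degenerate = a.std() == 0 and b.std() == 0 and len(set(a) | set(b)) == 1
        if degenerate:
            t_stat = mw_stat = 0.0
            t_p = mw_p = 1.0
        else:
            t_stat, t_p = stats.ttest_ind(a, b, equal_var=False)
            mw_stat, mw_p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append(
            {
                "cell_type": cell_type,
                "n_control": len(a),
                "n_hypoxia": len(b),
                "mean_control": a.mean(),
                "mean_hypoxia": b.mean(),
                "t_stat": float(t_stat),
                "t_p": float(t_p),
                "mw_stat": float(mw_stat),
                "mw_p": float(mw_p),
                "degenerate": degenerate,
            }
        )
    out = pd.DataFrame(rows)
    out["t_p_adj"] = multipletests(out["t_p"], alpha=alpha, method="fdr_bh")[1]
    out["mw_p_adj"] = multipletests(out["mw_p"], alpha=alpha, method="fdr_bh")[1]
    return out


class HeterogeneityModel:
    """Cluster-enrichment heterogeneity analysis of one study.

    Built from a raw genes x cells expression matrix (NaN non-detects) and
    a cell manifest with ``cell_id``, ``cell_type`` and ``strain`` columns;
    optionally an OCR table for the group-mean comparisons.  ``fit`` pools
    all cells, clusters them, and computes TES per strain group and RV per
    control/hypoxia pair.
    """

    def __init__(
        self,
        expression: pd.DataFrame,
        manifest: pd.DataFrame,
        ocr_table: pd.DataFrame | None = None,
    ) -> None:
        missing = {"cell_id", "cell_type", "strain"} - set(manifest.columns)
        if missing:
            raise DataError(f"manifest lacks column(s): {sorted(missing)}")
        unknown = set(expression.columns) - set(manifest["cell_id"])
        if unknown:
            raise DataError(f"expression cells not in manifest, e.g. {sorted(unknown)[:3]}")
        self.expression = expression
        self.manifest = manifest.set_index("cell_id", drop=False)
        self.ocr_table = ocr_table

    def fit(
        self, k: int = 10, linkage: str = "ward", metric: str = "euclidean"
    ) -> "HeterogeneityResults":
        normalized = normalize_expression(self.expression)
        assignment = hierarchical_cluster(normalized, k=k, linkage=linkage, metric=metric)
        manifest = self.manifest.loc[assignment.labels.index]
        groups = pd.Series(
            [
                ("c" if s == "control" else "h") + t
                for s, t in zip(manifest["strain"], manifest["cell_type"])
            ],
            index=assignment.labels.index,
        )
        enrichment = enrichment_scores(assignment, groups)

        rv_rows = []
        for cell_type in sorted(manifest["cell_type"].unique()):
            c_lab, h_lab = "c" + cell_type, "h" + cell_type
            if c_lab in enrichment.tes.index and h_lab in enrichment.tes.index:
                rv = relative_variability(enrichment.tes[c_lab], enrichment.tes[h_lab])
                rv_rows.append(
                    {
                        "cell_type": cell_type,
                        "tes_control": enrichment.tes[c_lab],
                        "tes_hypoxia": enrichment.tes[h_lab],
                        "rv": rv.raw,
                        "rv_rounded": rv.rounded,
                    }
                )
        rv_table = pd.DataFrame(rv_rows)
        comparisons = compare_groups(self.ocr_table) if self.ocr_table is not None else None
        return HeterogeneityResults(self, normalized, assignment, enrichment, rv_table, comparisons)


class HeterogeneityResults:
    """Results of a heterogeneity fit: clusters, TES per group, RV per pair."""

    def __init__(self, model, normalized, assignment, enrichment, rv_table, comparisons):
        self.model = model
        self.normalized = normalized
        self.assignment = assignment
        self.enrichment = enrichment
        self.rv_table = rv_table
        self.comparisons = comparisons

    def summary(self) -> str:
        a = self.assignment
        lines = [
            "Cluster-enrichment heterogeneity analysis",
            "=" * 54,
            f"cells: {a.n_total}   genes: {len(self.normalized.genes)}   "
            f"clusters: {a.k} ({a.linkage_method}/{a.distance_metric})",
            "",
            "TES per strain group (higher = less variable):",
        ]
        for g, v in self.enrichment.tes.items():
            lines.append(f"  {g:<10s} {v:6.2f}   (n={self.enrichment.group_sizes[g]})")
        if len(self.rv_table):
            lines.append("")
            lines.append("RV = TES_control / TES_hypoxia (RV < 1: variability decreased):")
            for _, r in self.rv_table.iterrows():
                lines.append(
                    f"  {r['cell_type']:<8s} {r['tes_control']:5.2f} / "
                    f"{r['tes_hypoxia']:5.2f} = {r['rv_rounded']:.2f}"
                )
        if self.comparisons is not None:
            lines.append("")
            lines.append("OCR group-mean comparisons (BH-adjusted):")
            for _, r in self.comparisons.iterrows():
                lines.append(
                    f"  {r['cell_type']:<8s} Welch p={r['t_p_adj']:.3f}  "
                    f"Mann-Whitney p={r['mw_p_adj']:.3f}"
                )
        return "\n".join(lines)
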