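"""OCR-augmented embeddings and aberrant-phenotype flagging.

Neither readout alone identifies a cell that is transcriptionally ordinary
but functionally extreme (or vice versa).  This module embeds cells by
expression (PCA, t-SNE), then fuses the respiration measurement in as a
third axis — the third PCA score of each cell is replaced by its robustly
scaled OCR — and flags two kinds of aberrant combined phenotypes:

``high-OCR-outlier``
    extreme OCR (|robust Z| above a threshold) in a cell whose expression
    profile sits comfortably inside its own cluster.
``non-respirer-cluster``
    a non-respiring cell whose expression profile is highly correlated with
    the other non-respirers, i.e. a transcriptionally coherent zero-OCR
    subgroup.

OCR is scaled by median/MAD over respiring cells because single-cell OCR
distributions are zero-inflated and right-skewed; non-respirers are pinned
at the bottom of the augmented axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .exceptions import ConfigurationError, DataError
from .heterogeneity import ClusterAssignment, NormalizedMatrix
from .ocr import NON_RESPIRING

FLAG_NONE = "none"
FLAG_HIGH_OCR = "high-OCR-outlier"
FLAG_NONRESPIRER = "non-respirer-cluster"

Z_THRESH = 2.5
Q_THRESH = 0.75
R_THRESH = 0.5


@dataclass
class EmbeddingResult:
    """Coordinates and flags from the combined-phenotype analysis."""

    pca_scores: pd.DataFrame
    explained_variance_fraction: np.ndarray
    tsne_coords: pd.DataFrame | None
    augmented_coords: pd.DataFrame | None
    flags: pd.Series | None
    metadata: dict = field(default_factory=dict)


def _cells_frame(data) -> pd.DataFrame:
    if isinstance(data, NormalizedMatrix):
        return data.cells_by_genes()
    if isinstance(data, pd.DataFrame):
        return data
    arr = np.asarray(data, dtype=float)
    return pd.DataFrame(arr)


def pca_embed(data, n_components: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Column-centered PCA with a deterministic sign convention.

    For each component the gene loading of largest magnitude is made
    positive, so the scores do not depend on solver sign choices and are
    invariant to gene-order permutations.  Components beyond the matrix
    rank are truncated with a warning.
    """
    x = _cells_frame(data)
    n_cells, n_genes = x.shape
    if n_components > min(n_cells, n_genes):
        raise ConfigurationError(
            f"n_components={n_components} exceeds min(cells, genes)={min(n_cells, n_genes)}"
        )
    xc = x.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(xc - xc.mean(axis=0))
    if n_components > rank:
        warnings.warn(
            f"requested {n_components} components but matrix rank is {rank}; truncating",
            stacklevel=2,
        )
        n_components = rank
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(xc)
    for j in range(n_components):
        i = int(np.argmax(np.abs(pca.components_[j])))
        if pca.components_[j, i] < 0:
            pca.components_[j] *= -1.0
            scores[:, j] *= -1.0
    cols = [f"PC{j + 1}" for j in range(n_components)]
    return pd.DataFrame(scores, index=x.index, columns=cols), pca.explained_variance_ratio_


def tsne_embed(
    data, perplexity: float = 15.0, seed: int = 0, n_iter: int = 1000
) -> tuple[pd.DataFrame, dict]:
    """2-D t-SNE embedding, deterministic given the seed."""
    x = _cells_frame(data)
    n = len(x)
    if perplexity >= (n - 1) / 3:
        raise ConfigurationError(
            f"perplexity {perplexity} too large for {n} cells (need < (n-1)/3)"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
        max_iter=n_iter,
    )
    coords = tsne.fit_transform(x.to_numpy(dtype=float))
    meta = {"perplexity": perplexity, "seed": seed, "n_iter": n_iter}
    return pd.DataFrame(coords, index=x.index, columns=["tSNE1", "tSNE2"]), meta


def robust_ocr_z(ocr: pd.Series, respiring: pd.Series | None = None) -> pd.Series:
    """Median/MAD Z score of OCR computed over respiring cells.

    Scale is 1.4826 * MAD (consistent with the SD under normality).  If the
    MAD is zero the SD is used; if that is zero too (constant OCR) the axis
    is all zeros with a warning.
    """
    ocr = ocr.astype(float)
    if respiring is None:
        respiring = ocr > 0
    resp_vals = ocr[respiring]
    if len(resp_vals) == 0:
        warnings.warn("no respiring cells; OCR axis set to zero", stacklevel=2)
        return pd.Series(0.0, index=ocr.index)
    med = float(resp_vals.median())
    mad = float((resp_vals - med).abs().median())
    scale = 1.4826 * mad
    if scale == 0:
        scale = float(resp_vals.std(ddof=0))
    if scale == 0:
        warnings.warn("constant OCR over respiring cells; axis set to zero", stacklevel=2)
        return pd.Series(0.0, index=ocr.index)
    return (ocr - med) / scale


def augment_with_ocr(
    pca_scores: pd.DataFrame, ocr: pd.Series, respiring: pd.Series | None = None
) -> pd.DataFrame:
    """3-D coordinates: (PC1, PC2, robust OCR Z).

    The third PCA axis is replaced by the respiration measurement so the
    combined view separates cells by function as well as transcription.
    Non-respirers are pinned at the minimum of the OCR axis.
    """
    ocr = ocr.reindex(pca_scores.index)
    if ocr.isna().any():
        raise DataError("OCR vector is not aligned to the PCA scores")
    if respiring is None:
        respiring = ocr > 0
    else:
        respiring = respiring.reindex(pca_scores.index).fillna(False)
    z = robust_ocr_z(ocr, respiring)
    if respiring.any() and (z[respiring] != 0).any():
        z.loc[~respiring] = float(z[respiring].min())
    out = pca_scores.iloc[:, :2].copy()
    out["OCRz"] = z
    return out


def _centroid_distances(expression: pd.DataFrame, labels: pd.Series) -> pd.Series:
    """Euclidean distance of each cell to its own cluster centroid."""
    dist = pd.Series(np.nan, index=expression.index)
    for lab, idx in labels.groupby(labels).groups.items():
        sub = expression.loc[idx]
        centroid = sub.mean(axis=0)
        dist.loc[idx] = np.sqrt(((sub - centroid) ** 2).sum(axis=1))
    return dist


def flag_aberrant_cells(
    augmented: pd.DataFrame,
    assignment: ClusterAssignment,
    expression: pd.DataFrame,
    ocr_table: pd.DataFrame,
    *,
    z_thresh: float = Z_THRESH,
    q_thresh: float = Q_THRESH,
    r_thresh: float = R_THRESH,
) -> pd.Series:
    """Flag aberrant combined phenotypes.

    Parameters
    ----------
    augmented
        Coordinates from :func:`augment_with_ocr` (the OCRz column is used).
    assignment
        Expression-space clustering of the same cells.
    expression
        Cells x genes normalized expression used for centroid distances and
        pairwise correlations.
    ocr_table
        DataFrame indexed by cell id with ``ocr_fmol_min`` and
        ``respirer_class`` columns; the class column fixes who counts as
        non-respiring so flags are invariant to rescaling the OCR values.
    """
    cells = augmented.index
    labels = assignment.labels.reindex(cells)
    expr = expression.reindex(cells)
    table = ocr_table.reindex(cells)
    if labels.isna().any() or expr.isna().all(axis=1).any() or table["ocr_fmol_min"].isna().any():
        raise DataError("flagging inputs are not aligned on the same cells")

    nonresp = table["respirer_class"] == NON_RESPIRING
    respiring = ~nonresp
    z = robust_ocr_z(table["ocr_fmol_min"], respiring)

    dist = _centroid_distances(expr, labels)
    q = dist.groupby(labels).transform(lambda d: d.quantile(q_thresh))
    high = respiring & (z.abs() > z_thresh) & (dist <= q)

    flags = pd.Series(FLAG_NONE, index=cells, name="flag")
    flags[high] = FLAG_HIGH_OCR

    n_nonresp = int(nonresp.sum())
    if n_nonresp >= 2:
        sub = expr.loc[nonresp]
        corr = np.corrcoef(sub.to_numpy(dtype=float))
        np.fill_diagonal(corr, np.nan)
        mean_corr = pd.Series(np.nanmean(corr, axis=1), index=sub.index)
        coherent = mean_corr > r_thresh
        flags[coherent.index[coherent]] = FLAG_NONRESPIRER
    elif n_nonresp > 0:
        warnings.warn(
            "fewer than 2 non-respirers; non-respirer-cluster flag skipped", stacklevel=2
        )
    return flags


class CombinedPhenotypeModel:
    """Combined transcription + respiration analysis of one study.

    Built from normalized expression (a NormalizedMatrix or cells x genes
    DataFrame), an OCR table indexed by cell id, and the pooled expression
    clustering.  ``fit`` computes the PCA and t-SNE embeddings, the
    OCR-augmented coordinates and the aberrance flags.
    """

    def __init__(
        self,
        expression,
        ocr_table: pd.DataFrame,
        assignment: ClusterAssignment,
    ) -> None:
        self.expression = _cells_frame(expression)
        self.ocr_table = ocr_table
        self.assignment = assignment

    def fit(
        self,
        n_components: int = 3,
        perplexity: float = 15.0,
        seed: int = 0,
        *,
        run_tsne: bool = True,
        z_thresh: float = Z_THRESH,
        q_thresh: float = Q_THRESH,
        r_thresh: float = R_THRESH,
    ) -> "CombinedPhenotypeResults":
        scores, evr = pca_embed(self.expression, n_components)
        ocr = self.ocr_table["ocr_fmol_min"].reindex(scores.index)
        respiring = (self.ocr_table["respirer_class"] != NON_RESPIRING).reindex(scores.index)
        augmented = augment_with_ocr(scores, ocr, respiring)
        flags = flag_aberrant_cells(
            augmented,
            self.assignment,
            self.expression,
            self.ocr_table,
            z_thresh=z_thresh,
            q_thresh=q_thresh,
            r_thresh=r_thresh,
        )
        tsne_coords, tsne_meta = (None, {})
        if run_tsne:
            tsne_coords, tsne_meta = tsne_embed(self.expression, perplexity, seed)
        result = EmbeddingResult(
            pca_scores=scores,
            explained_variance_fraction=evr,
            tsne_coords=tsne_coords,
            augmented_coords=augmented,
            flags=flags,
            metadata={
                "tsne": tsne_meta,
                "thresholds": {"z": z_thresh, "q": q_thresh, "r": r_thresh},
                "seed": seed,
            },
        )
        return CombinedPhenotypeResults(self, result)


class CombinedPhenotypeResults:
    """Embeddings, augmented coordinates and aberrance flags."""

    def __init__(self, model: CombinedPhenotypeModel, result: EmbeddingResult) -> None:
        self.model = model
        self.result = result

    @property
    def flags(self) -> pd.Series:
        return self.result.flags

    def to_frame(self) -> pd.DataFrame:
        """One row per cell: PCA, augmented and t-SNE coordinates + flag."""
        out = self.result.pca_scores.copy()
        out["OCRz"] = self.result.augmented_coords["OCRz"]
        if self.result.tsne_coords is not None:
            out[["tSNE1", "tSNE2"]] = self.result.tsne_coords
        out["flag"] = self.result.flags
        out.index.name = "cell_id"
        return out

    def summary(self) -> str:
        r = self.result
        counts = r.flags.value_counts()
        lines = [
            "Combined phenotype analysis",
            "=" * 44,
            f"cells: {len(r.pca_scores)}",
            "explained variance fractions: "
            + ", ".join(f"{v:.3f}" for v in r.explained_variance_fraction),
            f"high-OCR outliers:      {counts.get(FLAG_HIGH_OCR, 0)}",
            f"non-respirer cluster:   {counts.get(FLAG_NONRESPIRER, 0)}",
            f"unflagged:              {counts.get(FLAG_NONE, 0)}",
        ]
        return "\n".join(lines)

    def plot(self, axes=None):
        """Three panels: PCA, OCR-augmented (PC1 vs OCRz), t-SNE."""
        import matplotlib.pyplot as plt

        r = self.result
        if axes is None:
            n_panels = 3 if r.tsne_coords is not None else 2
            _, axes = plt.subplots(1, n_panels, figsize=(4 * n_panels, 3.5))
        colors = r.flags.map(
            {FLAG_NONE: "0.6", FLAG_HIGH_OCR: "crimson", FLAG_NONRESPIRER: "navy"}
        )
        axes[0].scatter(r.pca_scores["PC1"], r.pca_scores["PC2"], c=colors, s=12)
        axes[0].set_xlabel("PC1")
        axes[0].set_ylabel("PC2")
        axes[0].set_title("expression PCA")
        aug = r.augmented_coords
        axes[1].scatter(aug["PC1"], aug["OCRz"], c=colors, s=12)
        axes[1].set_xlabel("PC1")
        axes[1].set_ylabel("robust OCR Z")
        axes[1].set_title("OCR-augmented")
        if r.tsne_coords is not None and len(axes) > 2:
            axes[2].scatter(r.tsne_coords["tSNE1"], r.tsne_coords["tSNE2"], c=colors, s=12)
            axes[2].set_xlabel("tSNE1")
            axes[2].set_ylabel("tSNE2")
            axes[2].set_title("t-SNE")
        return axes
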