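"""Gradient saliency over input alignments and site-class enrichment.

The classifier's score Z is locally approximated by a first-order expansion
around an input alignment A0; the weight tensor of that linearization is the
input gradient w = dZ/dA evaluated at A0, computed by backpropagation with
dropout inactive and batch-norm frozen.  The saliency matrix takes the
maximum gradient magnitude across the five character channels at each
alignment position: M[i, j] = max_c |w[i, j, c]|.  The intercept of the
linearization is never needed and never materialized.

For comparison against per-codon site classes, the per-codon-column
aggregate takes the maximum over the 3 nucleotide columns and all taxon rows
(configurable to mean); enrichment of saliency in positively selected (S2)
columns is summarized by group means, their ratio, a Mann-Whitney rank-sum
statistic and a seeded column-label permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .encoding import EncodedExample
from .nn import Network


@dataclass
class SaliencyMap:
    """Non-negative importance matrix over the true (unpadded) alignment."""

    matrix: np.ndarray  # shape (n, L)
    gene_id: str
    codon_aggregate: np.ndarray  # shape (L/3,)

    @property
    def n_codon_columns(self) -> int:
        return self.codon_aggregate.shape[0]


def aggregate_codon_columns(matrix: np.ndarray, how: str = "max") -> np.ndarray:
    """Collapse an (n, L) saliency matrix to one value per codon column."""
    n, L = matrix.shape
    if L % 3 != 0:
        raise ValueError(f"saliency width {L} is not divisible by 3")
    per_codon = matrix.reshape(n, L // 3, 3)
    if how == "max":
        return per_codon.max(axis=(0, 2))
    if how == "mean":
        return per_codon.mean(axis=(0, 2))
    raise ValueError(f"unknown aggregation {how!r}; use 'max' or 'mean'")


def saliency_map(
    model: Network, example: EncodedExample, aggregate: str = "max"
) -> SaliencyMap:
    """Input-gradient saliency for one encoded alignment.

    The gradient is taken of the sigmoid output Z (pre-threshold) with
    respect to the one-hot input tensor; padded positions never enter
    because the example is evaluated at its true length.
    """
    if not hasattr(model, "input_gradient"):
        raise TypeError("model does not expose input gradients")
    x = example.tensor[np.newaxis].astype(np.float64)
    w = model.input_gradient(x)[0]  # (n, L, 5)
    matrix = np.abs(w).max(axis=2)
    return SaliencyMap(
        matrix=matrix,
        gene_id=example.gene_id,
        codon_aggregate=aggregate_codon_columns(matrix, how=aggregate),
    )


@dataclass
class EnrichmentSummary:
    mean_s2: float
    mean_other: float
    ratio: float
    rank_sum_u: float
    p_value: float
    n_s2: int
    n_other: int
    n_permutations: int

    @property
    def defined(self) -> bool:
        return self.n_s2 > 0 and self.n_other > 0


def site_class_enrichment(
    smap: SaliencyMap,
    column_classes: np.ndarray,
    n_permutations: int = 999,
    rng: np.random.Generator | int | None = None,
) -> EnrichmentSummary:
    """Is saliency elevated on S2 (omega > 1 candidate) codon columns?

    ``column_classes`` holds the per-codon-column site class (0, 1 or 2) and
    must match the map's codon-column count.  With no S2 columns (or no
    non-S2 columns) the summary is returned as undefined (NaN statistics)
    rather than raising.  The permutation p-value shuffles column labels and
    uses the add-one estimator, so its floor is 1/(n_permutations + 1).
    """
    classes = np.asarray(column_classes)
    values = smap.codon_aggregate
    if classes.shape[0] != values.shape[0]:
        raise ValueError(
            f"annotation length {classes.shape[0]} does not match "
            f"{values.shape[0]} codon columns"
        )
    is_s2 = classes == 2
    n_s2 = int(is_s2.sum())
    n_other = int((~is_s2).sum())
    if n_s2 == 0 or n_other == 0:
        return EnrichmentSummary(
            mean_s2=float("nan"), mean_other=float("nan"), ratio=float("nan"),
            rank_sum_u=float("nan"), p_value=float("nan"),
            n_s2=n_s2, n_other=n_other, n_permutations=0,
        )

    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    s2_vals, other_vals = values[is_s2], values[~is_s2]
    mean_s2 = float(s2_vals.mean())
    mean_other = float(other_vals.mean())
    ratio = mean_s2 / mean_other if mean_other > 0 else float("inf")
    u_stat = float(stats.mannwhitneyu(s2_vals, other_vals, alternative="greater").statistic)

    observed = mean_s2 - mean_other
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(values))
        perm_s2 = values[perm[:n_s2]]
        perm_other = values[perm[n_s2:]]
        if perm_s2.mean() - perm_other.mean() >= observed:
            exceed += 1
    p_value = (exceed + 1) / (n_permutations + 1)

    return EnrichmentSummary(
        mean_s2=mean_s2, mean_other=mean_other, ratio=ratio,
        rank_sum_u=u_stat, p_value=p_value,
        n_s2=n_s2, n_other=n_other, n_permutations=n_permutations,
    )


def saliency_table(smap: SaliencyMap):
    """Long-form (row, column, value) DataFrame, e.g. for a TSV dump."""
    import pandas as pd

    n, L = smap.matrix.shape
    rows, cols = np.meshgrid(np.arange(n), np.arange(L), indexing="ij")
    return pd.DataFrame(
        {
            "gene_id": smap.gene_id,
            "row": rows.ravel(),
            "column": cols.ravel(),
            "saliency": smap.matrix.ravel(),
        }
    )


def plot_saliency(
    smap: SaliencyMap,
    column_classes: np.ndarray | None = None,
    path: str | None = None,
):
    """Heatmap of the saliency matrix with an optional site-class track."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_panels = 2 if column_classes is not None else 1
    fig, axes = plt.subplots(
        n_panels, 1, figsize=(10, 3 + n_panels),
        gridspec_kw={"height_ratios": [1, 4][-n_panels:]}, squeeze=False,
    )
    row = 0
    if column_classes is not None:
        track = np.repeat(np.asarray(column_classes)[np.newaxis, :], 3, axis=1)
        axes[row, 0].imshow(track, aspect="auto", cmap="coolwarm", vmin=0, vmax=2)
        axes[row, 0].set_yticks([])
        axes[row, 0].set_title("site class (blue S0, white S1, red S2)")
        row += 1
    im = axes[row, 0].imshow(smap.matrix, aspect="auto", cmap="viridis")
    axes[row, 0].set_xlabel("alignment column (nt)")
    axes[row, 0].set_ylabel("taxon row")
    fig.colorbar(im, ax=axes[row, 0], label="saliency")
    fig.suptitle(f"saliency map: {smap.gene_id}")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
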