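"""Cross-matrix statistical comparison.

Four tools for asking whether two matrix types make the same predictions:

* a chi-square goodness-of-fit test comparing a matrix's (hits, borderlines,
  misses) tallies against those of a reference matrix (conventionally the
  mononucleotide model ``m``), df = 2;
* per-nucleotide prediction vectors — the concatenated coverage counts over
  all peaks — compared by Pearson correlation;
* agglomerative hierarchical clustering of matrix types on 1 - r distances,
  exported as a newick tree;
* subsampling cross-validation of the RZ score over random half-sized peak
  subsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform
from scipy.stats import chi2 as chi2_dist

from .peaks import PredictionResult

__all__ = [
    "Chi2Result",
    "chi_square_vs_reference",
    "concat_prediction_vectors",
    "pearson_correlation",
    "cluster_matrix_types",
    "linkage_to_newick",
    "cross_validate_rz_from_z",
    "cross_validate_rz",
]


@dataclass(frozen=True)
class Chi2Result:
    """Chi-square comparison of (hits, borderlines, misses) tallies."""

    chi2: float
    df: int
    p_value: float

    @property
    def significance_band(self) -> str:
        if self.p_value < 0.01:
            return "p<0.01"
        if self.p_value < 0.05:
            return "p<0.05"
        return "ns"


def chi_square_vs_reference(
    observed: tuple[int, int, int], expected: tuple[int, int, int]
) -> Chi2Result:
    """Pearson chi-square over the three outcome categories.

    ``observed`` are the (hits, borderlines, misses) of the matrix under
    test, ``expected`` those of the reference matrix; both must tally the
    same number of peaks.  Categories with expected count 0 are dropped
    (the statistic is undefined there) with the degrees of freedom reduced
    accordingly and a warning issued.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != (3,) or exp.shape != (3,):
        raise ValueError("observed and expected must be (hits, borderlines, misses) triples")
    if not np.isclose(obs.sum(), exp.sum()):
        raise ValueError(
            f"observed total {obs.sum():g} != expected total {exp.sum():g}: "
            "both tallies must cover the same peaks"
        )
    keep = exp > 0
    if not np.all(keep):
        warnings.warn(
            f"dropping {int((~keep).sum())} categor(ies) with expected count 0",
            stacklevel=2,
        )
    obs, exp = obs[keep], exp[keep]
    df = max(len(obs) - 1, 1)
    stat = float(((obs - exp) ** 2 / exp).sum())
    return Chi2Result(chi2=stat, df=df, p_value=float(chi2_dist.sf(stat, df)))


def concat_prediction_vectors(results: list[PredictionResult]) -> np.ndarray:
    """Concatenate per-peak coverage vectors into one length N*l_c vector.

    Element ``i*l_c + j`` is the number of distinct predicted sites covering
    position j of peak i.  Peaks must share one length and the ordering
    must be held consistent across matrix types by the caller.
    """
    if not results:
        raise ValueError("no prediction results to concatenate")
    l_c = len(results[0].coverage)
    for res in results:
        if len(res.coverage) != l_c:
            raise ValueError(
                f"peak {res.peak_id!r} has coverage length "
                f"{len(res.coverage)}, expected {l_c}"
            )
    return np.concatenate([res.coverage for res in results])


def pearson_correlation(X, Y) -> float:
    """Pearson product-moment correlation of two prediction vectors.

    A pair involving a constant vector has no defined correlation; it is
    reported as 0 with a warning (such vectors arise at thresholds where a
    matrix predicts nothing anywhere).
    """
    x = np.asarray(X, dtype=float)
    y = np.asarray(Y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"vector shapes differ: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("correlation requires vectors of length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn(
            "constant prediction vector: correlation undefined, reporting 0",
            stacklevel=2,
        )
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def cluster_matrix_types(
    distance: np.ndarray, labels: list[str], method: str = "average"
) -> str:
    """Agglomerative clustering of matrix types; returns a newick tree.

    ``distance`` is a symmetric matrix (zero diagonal) of 1 - r distances
    in [0, 2].  The tree is ultrametric: each internal node sits at half its
    merge distance (so the path length between two leaves equals their
    cophenetic distance) and branch lengths are differences of node heights.
    """
    d = np.asarray(distance, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"distance matrix must be square, got shape {d.shape}")
    if d.shape[0] != len(labels):
        raise ValueError(
            f"{len(labels)} labels for a {d.shape[0]}x{d.shape[0]} matrix"
        )
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if d.shape[0] == 1:
        return f"{labels[0]};"
    Z = linkage(squareform(d, checks=False), method=method)
    return linkage_to_newick(Z, labels)


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a newick string with branch lengths."""
    tree = to_tree(Z)

    def render(node, parent_height: float) -> str:
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.10g}"
        height = node.dist / 2
        left = render(node.left, height)
        right = render(node.right, height)
        return f"({left},{right}):{parent_height - height:.10g}"

    root_height = tree.dist / 2
    left = render(tree.left, root_height)
    right = render(tree.right, root_height)
    return f"({left},{right});"


def cross_validate_rz_from_z(
    per_peak_z,
    fraction: float = 0.5,
    replicates: int = 100,
    seed: int = 0,
) -> dict:
    """Cross-validate RZ by subsampling peaks without replacement.

    Each replicate draws a uniform subset of ``floor(fraction * N)`` peaks
    and recomputes RZ as the mean of their z values (z per peak does not
    depend on which other peaks are present).  Returns the replicate RZ
    values with their mean and standard deviation alongside the full-set RZ.
    """
    z = np.asarray(per_peak_z, dtype=float)
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    size = int(fraction * z.size)
    if size == 0:
        raise ValueError(
            f"fraction {fraction} of {z.size} peaks gives an empty subset"
        )
    rng = np.random.default_rng(seed)
    reps = np.array(
        [z[rng.choice(z.size, size=size, replace=False)].mean() for _ in range(replicates)]
    )
    return {
        "replicate_rz": reps,
        "mean": float(reps.mean()),
        "std": float(reps.std(ddof=1)) if replicates > 1 else 0.0,
        "full_rz": float(z.mean()),
        "subset_size": size,
    }


def cross_validate_rz(
    peaks,
    scrambles,
    wm,
    tau: float,
    fraction: float = 0.5,
    replicates: int = 100,
    seed: int = 0,
) -> dict:
    """Cross-validated RZ from raw peaks (computes per-peak z once)."""
    from .evaluation import rz_score

    full = rz_score(peaks, scrambles, wm, tau)
    out = cross_validate_rz_from_z(
        full.per_peak_z, fraction=fraction, replicates=replicates, seed=seed
    )
    out["full_result"] = full
    return out
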