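"""Statsmodels-style front end: a model built from data, fit to results.

:class:`GappedMatrixAnalysis` bundles the three inputs — aligned known
binding sites, ChIP peaks, and a background sequence — with the family of
gapped n-mer patterns to evaluate.  ``fit()`` estimates one weight matrix
per pattern, sweeps a threshold grid derived from the known-site score
distribution, scans the true peaks and their scrambled nulls, and returns a
:class:`GappedMatrixResults` carrying per-pattern AUROC, RZ tables,
per-peak z values, and everything needed for the downstream statistical
comparisons (chi-square vs a reference matrix, prediction-vector
correlations, hierarchical clustering, cross-validation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import ROCCurve, RZResult, roc_and_auroc, rz_from_counts
from .motif import AlignedSites, BackgroundModel, WeightMatrix, build_weight_matrix, estimate_background
from .patterns import GappedNmer, decode_type_id, enumerate_patterns
from .peaks import ChipPeak, PredictionResult, predict_sites, prepare_peaks, scramble_peak
from .stats import (
    Chi2Result,
    chi_square_vs_reference,
    cluster_matrix_types,
    concat_prediction_vectors,
    cross_validate_rz_from_z,
    pearson_correlation,
)
from .thresholds import site_score_distribution, threshold_grid

__all__ = ["GappedMatrixAnalysis", "GappedMatrixResults"]

logger = logging.getLogger(__name__)


def _xkey(x: float) -> float:
    return round(float(x), 10)


def _counts_at(sorted_scores: np.ndarray, tau: float) -> int:
    """Number of valid windows scoring >= tau (scores sorted ascending)."""
    return int(sorted_scores.size - np.searchsorted(sorted_scores, tau, side="left"))


class GappedMatrixAnalysis:
    """Evaluate gapped n-mer weight matrices on ChIP peaks.

    Parameters
    ----------
    sites :
        Aligned known binding sites (an :class:`AlignedSites` or a list of
        equal-length ACGT strings).
    peaks :
        Raw ChIP peaks as (id, sequence) pairs; trimmed/filtered to the
        central ``center_length`` bases at construction.
    background :
        Background nucleotide sequence (string or list of record strings);
        word frequencies are estimated per pattern.
    patterns :
        'all' (every pattern up to ``max_frame``, 32 by default), or a list
        of type IDs / pattern strings.
    center_length :
        Prepared peak length l_c (default 100).
    n_scrambles :
        Scrambled nulls per peak, P (default 100).
    seed :
        Seed for the scramble permutations.
    both_strands :
        Score each window on both strands and keep the maximum (default
        off: forward-strand scanning only).
    """

    def __init__(
        self,
        sites,
        peaks: list[tuple[str, str]],
        background,
        patterns="all",
        max_frame: int = 6,
        center_length: int = 100,
        n_scrambles: int = 100,
        seed: int = 0,
        both_strands: bool = False,
    ):
        self.sites = sites if isinstance(sites, AlignedSites) else AlignedSites(sites)
        if max_frame > self.sites.site_length:
            raise ValueError(
                f"max_frame {max_frame} exceeds the site length "
                f"{self.sites.site_length}"
            )
        if center_length < self.sites.site_length:
            raise ValueError(
                f"center_length {center_length} is shorter than the site "
                f"length {self.sites.site_length}"
            )
        self.patterns = self._resolve_patterns(patterns, max_frame)
        self.max_frame = max_frame
        self.center_length = center_length
        self.n_scrambles = n_scrambles
        self.seed = seed
        self.both_strands = both_strands
        self.background = (
            [background] if isinstance(background, str) else list(background)
        )
        self.peaks: list[ChipPeak] = (
            peaks
            if peaks and isinstance(peaks[0], ChipPeak)
            else prepare_peaks(list(peaks), center_length)
        )
        self.scrambles = [
            scramble_peak(p, n_scrambles, seed) for p in self.peaks
        ]

    @staticmethod
    def _resolve_patterns(patterns, max_frame: int) -> list[GappedNmer]:
        if isinstance(patterns, str) and patterns == "all":
            return enumerate_patterns(max_frame)
        out = []
        for p in patterns:
            if isinstance(p, GappedNmer):
                out.append(p)
            elif isinstance(p, int):
                out.append(decode_type_id(p, max_frame))
            else:
                out.append(GappedNmer(str(p)))
        return out

    @classmethod
    def from_files(
        cls,
        site_path,
        peak_path,
        background_path,
        genome_path=None,
        **kwargs,
    ) -> "GappedMatrixAnalysis":
        """Build the model from FASTA/text/BED inputs on disk."""
        from .io import iter_background_records, read_aligned_sites, read_peaks

        return cls(
            sites=read_aligned_sites(site_path),
            peaks=read_peaks(peak_path, genome_path),
            background=list(iter_background_records(background_path)),
            **kwargs,
        )

    def fit(self, threshold_step: float = 0.25) -> "GappedMatrixResults":
        """Estimate and evaluate every selected matrix.

        For each pattern: estimate background word frequencies, build the
        weight matrix, derive the threshold grid from the known-site score
        distribution, scan true and scrambled peaks, and tabulate TPR/FPR,
        AUROC, and RZ (with per-peak z values) at every grid position.
        """
        per_pattern: dict[str, dict] = {}
        for pattern in self.patterns:
            logger.info("fitting pattern %s (ID %d)", pattern.pattern, pattern.type_id)
            bg = estimate_background(self.background, pattern)
            wm = build_weight_matrix(self.sites, pattern, bg)
            site_scores = site_score_distribution(self.sites, wm)
            grid = threshold_grid(site_scores, threshold_step)

            true_scores = [
                wm.window_scores(p.sequence)[0] for p in self.peaks
            ]
            true_sorted = [np.sort(s[~np.isnan(s)]) for s in true_scores]
            scram_sorted = [
                [
                    np.sort(sc[~np.isnan(sc)])
                    for sc in (wm.window_scores(s)[0] for s in sset.scrambles)
                ]
                for sset in self.scrambles
            ]

            rates: list[tuple[float, float]] = []
            rz_by_x: dict[float, RZResult] = {}
            tau_by_x: dict[float, float] = {}
            for x, tau in grid:
                r_true = np.array([_counts_at(s, tau) for s in true_sorted])
                r_scram = np.array(
                    [[_counts_at(s, tau) for s in row] for row in scram_sorted]
                )
                tpr = float((r_true >= 1).mean())
                fpr = float((r_scram >= 1).mean())
                rates.append((fpr, tpr))
                rz_by_x[_xkey(x)] = rz_from_counts(r_true, r_scram, tau)
                tau_by_x[_xkey(x)] = tau
            roc = roc_and_auroc(rates)
            per_pattern[pattern.pattern] = {
                "pattern": pattern,
                "background": bg,
                "weight_matrix": wm,
                "site_scores": site_scores,
                "grid": grid,
                "tau_by_x": tau_by_x,
                "rates": rates,
                "roc": roc,
                "rz_by_x": rz_by_x,
                "true_window_scores": true_scores,
            }
        return GappedMatrixResults(model=self, per_pattern=per_pattern)


@dataclass
class GappedMatrixResults:
    """Fitted matrices and their evaluation tables.

    Access per-pattern objects through ``weight_matrices``, ``roc_curves``
    and ``rz_results``; tabulated views through ``auroc``, ``rz_table`` and
    ``summary()``; statistical comparisons through ``chi2_table``,
    ``correlation_matrix``, ``cluster`` and ``cross_validate``.
    """

    model: GappedMatrixAnalysis
    per_pattern: dict[str, dict]
    _vector_cache: dict = field(default_factory=dict, repr=False)

    # -- basic accessors -------------------------------------------------

    @property
    def pattern_names(self) -> list[str]:
        return list(self.per_pattern)

    @property
    def weight_matrices(self) -> dict[str, WeightMatrix]:
        return {k: v["weight_matrix"] for k, v in self.per_pattern.items()}

    @property
    def backgrounds(self) -> dict[str, BackgroundModel]:
        return {k: v["background"] for k, v in self.per_pattern.items()}

    @property
    def roc_curves(self) -> dict[str, ROCCurve]:
        return {k: v["roc"] for k, v in self.per_pattern.items()}

    @property
    def auroc(self) -> pd.Series:
        return pd.Series(
            {k: v["roc"].auroc for k, v in self.per_pattern.items()},
            name="AUROC",
        )

    @property
    def x_grid(self) -> list[float]:
        first = next(iter(self.per_pattern.values()))
        return sorted(first["rz_by_x"])

    def rz_result(self, pattern: str, x: float) -> RZResult:
        return self.per_pattern[pattern]["rz_by_x"][_xkey(x)]

    @property
    def rz_table(self) -> pd.DataFrame:
        """RZ scores, one row per pattern, one column per threshold position."""
        xs = self.x_grid
        data = {
            k: [v["rz_by_x"][x].rz for x in xs]
            for k, v in self.per_pattern.items()
        }
        return pd.DataFrame.from_dict(
            data, orient="index", columns=[f"RZ@x={x:g}" for x in xs]
        )

    def threshold_table(self) -> pd.DataFrame:
        """Score threshold tau behind each (pattern, x) grid cell."""
        xs = self.x_grid
        data = {
            k: [v["tau_by_x"][x] for x in xs]
            for k, v in self.per_pattern.items()
        }
        return pd.DataFrame.from_dict(
            data, orient="index", columns=[f"tau@x={x:g}" for x in xs]
        )

    def summary(self) -> pd.DataFrame:
        """Per-pattern overview: ID, mu, frames, AUROC, RZ across the grid."""
        rows = []
        for name, entry in self.per_pattern.items():
            pat: GappedNmer = entry["pattern"]
            row = {
                "type_id": pat.type_id,
                "pattern": name,
                "mu": pat.mu,
                "frame_length": pat.frame_length,
                "n_frames": entry["weight_matrix"].n_frames,
                "AUROC": entry["roc"].auroc,
            }
            for x in self.x_grid:
                row[f"RZ@x={x:g}"] = entry["rz_by_x"][x].rz
            rows.append(row)
        return pd.DataFrame(rows).set_index("type_id")

    # -- statistical comparisons ----------------------------------------

    def chi2_vs_reference(
        self, pattern: str, x: float, reference: str = "m"
    ) -> Chi2Result:
        """Chi-square of a pattern's (hits, borderlines, misses) vs a reference."""
        obs = self.rz_result(pattern, x)
        exp = self.rz_result(reference, x)
        return chi_square_vs_reference(
            (obs.hits, obs.borderlines, obs.misses),
            (exp.hits, exp.borderlines, exp.misses),
        )

    def chi2_table(self, x: float, reference: str = "m") -> pd.DataFrame:
        """Chi-square vs the reference for every non-reference pattern at x."""
        rows = []
        for name in self.pattern_names:
            if name == reference:
                continue
            res = self.chi2_vs_reference(name, x, reference)
            rows.append(
                {
                    "pattern": name,
                    "x": x,
                    "chi2": res.chi2,
                    "df": res.df,
                    "p_value": res.p_value,
                    "band": res.significance_band,
                }
            )
        return pd.DataFrame(rows).set_index("pattern")

    def prediction_vector(self, pattern: str, x: float) -> np.ndarray:
        """Concatenated per-nucleotide coverage over all peaks at position x."""
        key = (pattern, _xkey(x))
        if key not in self._vector_cache:
            entry = self.per_pattern[pattern]
            tau = entry["tau_by_x"][_xkey(x)]
            wm = entry["weight_matrix"]
            results = [
                predict_sites(
                    p.sequence, wm, tau, p.peak_id, self.model.both_strands
                )
                for p in self.model.peaks
            ]
            self._vector_cache[key] = concat_prediction_vectors(results)
        return self._vector_cache[key]

    def predictions(self, pattern: str, x: float) -> list[PredictionResult]:
        """Per-peak predicted sites for one pattern at grid position x."""
        entry = self.per_pattern[pattern]
        tau = entry["tau_by_x"][_xkey(x)]
        wm = entry["weight_matrix"]
        return [
            predict_sites(p.sequence, wm, tau, p.peak_id, self.model.both_strands)
            for p in self.model.peaks
        ]

    def correlation_matrix(self, x: float) -> pd.DataFrame:
        """Pairwise Pearson correlation of prediction vectors at position x."""
        names = self.pattern_names
        vecs = {n: self.prediction_vector(n, x) for n in names}
        r = np.eye(len(names))
        for i, a in enumerate(names):
            for j in range(i + 1, len(names)):
                r[i, j] = r[j, i] = pearson_correlation(vecs[a], vecs[names[j]])
        return pd.DataFrame(r, index=names, columns=names)

    def distance_matrix(self, x: float) -> pd.DataFrame:
        """1 - r distances between matrix types at position x."""
        corr = self.correlation_matrix(x)
        d = 1.0 - corr
        np.fill_diagonal(d.values, 0.0)
        return d

    def cluster(self, x: float, method: str = "average") -> str:
        """Agglomerative clustering of matrix types; newick string."""
        d = self.distance_matrix(x)
        return cluster_matrix_types(d.values, list(d.index), method=method)

    def cross_validate(
        self,
        pattern: str,
        x: float,
        fraction: float = 0.5,
        replicates: int = 100,
        seed: int | None = None,
    ) -> dict:
        """Subsampling cross-validation of RZ for one pattern at position x."""
        res = self.rz_result(pattern, x)
        return cross_validate_rz_from_z(
            res.per_peak_z,
            fraction=fraction,
            replicates=replicates,
            seed=self.model.seed if seed is None else seed,
        )

    # -- plotting --------------------------------------------------------

    def plot_roc(self, patterns=None, ax=None):
        """ROC curves for the selected patterns (all by default)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for name in patterns or self.pattern_names:
            pts = self.per_pattern[name]["roc"].points
            ax.plot([p[0] for p in pts], [p[1] for p in pts], label=name)
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        if len(patterns or self.pattern_names) <= 10:
            ax.legend(fontsize="small")
        return ax

    def plot_heatmap(self, ax=None):
        """Heatmap of AUROC and RZ across the threshold grid, per pattern."""
        import matplotlib.pyplot as plt

        table = pd.concat([self.auroc, self.rz_table], axis=1)
        if ax is None:
            _, ax = plt.subplots(
                figsize=(2 + table.shape[1], 0.3 * len(table) + 1)
            )
        im = ax.imshow(table.values, aspect="auto", cmap="RdYlGn")
        ax.set_xticks(range(table.shape[1]), table.columns, rotation=45, ha="right")
        ax.set_yticks(range(len(table)), table.index)
        ax.figure.colorbar(im, ax=ax)
        return ax
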