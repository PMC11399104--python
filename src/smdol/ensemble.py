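"""Ensemble (bulk) degree-of-labeling arithmetic and copy-number tools.

For antibody conjugates the labeling degree is measured in bulk by
absorbance spectroscopy: the label's absorbance at its peak relative to
the protein's 280 nm absorbance (corrected for the label's own 280 nm
contribution) gives the mean number of labels per molecule,

    DOL = Abs_label * eps_target / (eps_label * (Abs_280 - c280 * Abs_label)).

Combined with the measured distribution of label counts among *labeled*
molecules (whose mean is the pseudo-ensemble DOL), the unlabeled
fraction follows from ensemble = (1 - unlabeled) * labeled_mean.  The
bulk DOL finally converts per-cluster labeled-molecule counts into total
copy numbers, with log-normal summaries for cluster-size distributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "AbsorbanceRecord",
    "ensemble_dol",
    "pseudo_ensemble_dol",
    "unlabeled_fraction",
    "copies_per_cluster",
    "fit_lognormal",
    "LogNormalFit",
    "round_percent",
]


@dataclass(frozen=True)
class AbsorbanceRecord:
    """Absorbance measurement of a labeled protein.

    ``abs_label`` is the absorbance at the label's peak (e.g. 652 nm for
    a silicon-rhodamine dye), ``correction_280`` the label's relative
    absorbance at 280 nm.  Extinctions are molar (1/M/cm).
    """

    abs_280: float
    abs_label: float
    eps_target: float
    eps_label: float
    correction_280: float = 0.0

    def __post_init__(self) -> None:
        if self.eps_target <= 0 or self.eps_label <= 0:
            raise ValueError("extinction coefficients must be positive")
        if self.abs_280 < 0 or self.abs_label < 0:
            raise ValueError("absorbances must be >= 0")
        if self.abs_280 - self.correction_280 * self.abs_label <= 0:
            raise ValueError("corrected protein absorbance must be positive")


def ensemble_dol(record: AbsorbanceRecord) -> float:
    """Mean labels per molecule from a bulk absorbance measurement."""
    protein = record.abs_280 - record.correction_280 * record.abs_label
    return record.abs_label * record.eps_target / (record.eps_label * protein)


def pseudo_ensemble_dol(distribution: dict[int, float]) -> float:
    """Mean label count among labeled molecules, sum_k k * fraction(k).

    ``distribution`` maps integer label counts k >= 1 to the fraction of
    labeled molecules carrying k labels; fractions must sum to 1.
    """
    if not distribution:
        raise ValueError("empty label-number distribution")
    ks = np.array(list(distribution.keys()), dtype=float)
    fs = np.array(list(distribution.values()), dtype=float)
    if np.any(ks < 1) or np.any(fs < 0):
        raise ValueError("label counts must be >= 1 and fractions >= 0")
    if abs(fs.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fs.sum():.12f}")
    return float(np.sum(ks * fs))


def unlabeled_fraction(ensemble: float, labeled_mean: float) -> float:
    """Fraction of molecules carrying no label.

    From ensemble = (1 - unlabeled) * labeled_mean:
    unlabeled = 1 - ensemble / labeled_mean.
    """
    if ensemble <= 0:
        raise ValueError("ensemble DOL must be positive")
    if labeled_mean < ensemble:
        raise ValueError(
            "labeled-molecule mean below the ensemble DOL: inconsistent inputs"
        )
    return 1.0 - ensemble / labeled_mean


def round_percent(fraction: float) -> int:
    """Round a fraction to the nearest integer percent, half away from zero."""
    pct = fraction * 100.0
    return int(np.sign(pct) * np.floor(abs(pct) + 0.5))


def copies_per_cluster(
    cluster_counts,
    dol: float,
    dol_se: float = 0.0,
    count_se=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Extrapolate labeled-molecule counts to total copy numbers.

    copies = count / dol; the standard error combines the count's and
    the DOL's relative errors in quadrature.  Returns (copies, se).
    """
    if not (0 < dol <= 1):
        raise ValueError("dol must be in (0, 1]")
    counts = np.asarray(cluster_counts, dtype=float)
    copies = counts / dol
    if count_se is None:
        count_se = np.zeros_like(counts)
    count_se = np.broadcast_to(np.asarray(count_se, dtype=float), counts.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.sqrt(
            np.where(counts > 0, (count_se / counts) ** 2, 0.0) + (dol_se / dol) ** 2
        )
    return copies, copies * rel


class LogNormalFit(NamedTuple):
    mu_log: float
    sigma_log: float
    geometric_mean: float
    se_geometric_mean: float


def fit_lognormal(values) -> LogNormalFit:
    """Maximum-likelihood log-normal fit of positive values.

    mu/sigma are the mean and (MLE, 1/n) SD of the log values; the
    geometric mean is exp(mu) with a delta-method standard error
    gm * sigma / sqrt(n).
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 3:
        raise ValueError("need at least 3 values")
    if np.any(vals <= 0) or not np.all(np.isfinite(vals)):
        raise ValueError("all values must be positive and finite")
    logs = np.log(vals)
    mu = float(np.mean(logs))
    sigma = float(np.std(logs))  # MLE (1/n)
    gm = float(np.exp(mu))
    se = gm * sigma / np.sqrt(vals.size)
    return LogNormalFit(mu, sigma, gm, se)
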