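"""Reader-agreement and cohort statistics.

Covers the study-style statistics around endoleak reading: linearly weighted
Cohen's kappa on per-patient endoleak counts (with a bootstrap interval),
exact/approximate Wilcoxon signed-rank and Mann-Whitney U tests, medians with
interquartile ranges, majority-consensus lesion totals, and the DLP ->
effective-dose conversion (abdominal factor 0.015 mSv/(mGy cm)).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

try:  # py3.9+: importlib.resources.files
    from importlib.resources import files as _res_files
except ImportError:  # pragma: no cover
    _res_files = None

__all__ = [
    "ReaderTable",
    "DoseRecord",
    "TestResult",
    "weighted_kappa",
    "kappa_ci",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "median_iqr",
    "effective_dose",
    "consensus_counts",
    "load_reader_table",
    "load_dose_table",
]

#: Abdominal CT conversion factor, mSv per mGy*cm.
DOSE_CONVERSION_FACTOR = 0.015


# ---------------------------------------------------------------------------
# Weighted kappa

def _kappa_from_lists(a: np.ndarray, b: np.ndarray) -> float:
    k = int(max(a.max(initial=0), b.max(initial=0))) + 1
    if k == 1:
        return 1.0  # both raters constant at the same single category
    conf = np.zeros((k, k))
    for ai, bi in zip(a, b):
        conf[ai, bi] += 1
    conf /= conf.sum()
    idx = np.arange(k)
    w = 1.0 - np.abs(idx[:, None] - idx[None, :]) / (k - 1)
    po = float((w * conf).sum())
    pe = float((w * np.outer(conf.sum(axis=1), conf.sum(axis=0))).sum())
    if pe >= 1.0:
        return 1.0
    return (po - pe) / (1.0 - pe)


def weighted_kappa(a, b) -> float:
    """Linearly weighted Cohen's kappa for ordinal ratings.

    The shared category set is the integers 0..max(observed across both
    raters); weights are ``1 - |i - j| / (k - 1)``.  Returns 1.0 when both
    raters are constant and equal (chance agreement saturates).
    """
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("rating lists must be 1D and of equal length")
    if a.size < 2:
        raise ValueError("need at least two rated subjects")
    if a.min(initial=0) < 0 or b.min(initial=0) < 0:
        raise ValueError("ratings must be non-negative integers")
    return float(_kappa_from_lists(a, b))


def kappa_ci(a, b, n_boot: int = 2000, seed: int = 0,
             level: float = 0.95) -> tuple[float, float]:
    """Percentile-bootstrap CI for the weighted kappa (resampling patients
    jointly), deterministic for a given seed."""
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    weighted_kappa(a, b)  # validate inputs
    rng = np.random.default_rng(seed)
    n = a.size
    boots = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boots[i] = _kappa_from_lists(a[idx], b[idx])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Nonparametric tests

@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float
    n: int
    method: str
    degenerate: bool = False  # e.g. all paired differences were zero


def _signed_rank_enumeration(d: np.ndarray) -> TestResult:
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns;
    handles tied |d| via average ranks."""
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    mu = ranks.sum() / 2.0
    signs = np.array(list(product((0.0, 1.0), repeat=n)))
    w_all = signs @ ranks
    p_lo = np.mean(w_all <= w_obs)
    p_hi = np.mean(w_all >= w_obs)
    p = min(1.0, 2.0 * min(p_lo, p_hi))
    return TestResult(w_obs, float(p), n, "exact-enumeration")


def wilcoxon_signed_rank(x, y) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped before ranking.  Exact p for n <= 25 without
    ties in |differences| (and via full sign enumeration for tied samples up
    to n = 14); otherwise the normal approximation with tie correction and no
    continuity correction.  All differences zero returns p = 1 with the
    ``degenerate`` flag set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired samples must be 1D and of equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult(0.0, 1.0, 0, "degenerate", degenerate=True)
    has_ties = np.unique(np.abs(d)).size < n
    if not has_ties and n <= 25:
        res = sps.wilcoxon(d, zero_method="wilcox", method="exact")
        return TestResult(float(res.statistic), float(res.pvalue), n, "exact")
    if has_ties and n <= 14:
        return _signed_rank_enumeration(d)
    res = sps.wilcoxon(d, zero_method="wilcox", method="approx", correction=False)
    return TestResult(float(res.statistic), float(res.pvalue), n, "normal-approx")


def mann_whitney_u(g1, g2) -> TestResult:
    """Two-sided Mann-Whitney U test; exact for small tie-free samples,
    tie-corrected normal approximation (no continuity correction) otherwise."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.size == 0 or g2.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([g1, g2])
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and g1.size + g2.size <= 25:
        res = sps.mannwhitneyu(g1, g2, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = sps.mannwhitneyu(g1, g2, alternative="two-sided",
                               method="asymptotic", use_continuity=False)
        method = "normal-approx"
    return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)),
                      g1.size + g2.size, method)


def median_iqr(values) -> tuple[float, float, float]:
    """(median, Q1, Q3) with linear interpolation between order statistics."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("values must be non-empty")
    med, q1, q3 = np.percentile(values, [50, 25, 75])
    return float(med), float(q1), float(q3)


# ---------------------------------------------------------------------------
# Dose

@dataclass(frozen=True)
class DoseRecord:
    dlp: float                                  # mGy*cm
    conversion_factor: float = DOSE_CONVERSION_FACTOR

    def __post_init__(self) -> None:
        if self.dlp < 0 or self.conversion_factor < 0:
            raise ValueError("DLP and conversion factor must be >= 0")

    @property
    def effective_dose(self) -> float:          # mSv
        return self.dlp * self.conversion_factor


def effective_dose(dlp: float, factor: float = DOSE_CONVERSION_FACTOR) -> float:
    """Effective dose in mSv from a dose-length product in mGy*cm."""
    return DoseRecord(dlp, factor).effective_dose


# ---------------------------------------------------------------------------
# Reader tables

class ReaderTable:
    """Per-patient endoleak counts by (technique, observer, reading session),
    plus the triphasic-CTA reference column.

    Long CSV format: ``patient_id, tech, observer, reading, count``; the
    reference rows use ``tech=triphasic, observer=ref``.
    """

    REFERENCE_TECH = "triphasic"

    def __init__(self, df: pd.DataFrame):
        required = {"patient_id", "tech", "observer", "reading", "count"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"reader table missing columns: {sorted(missing)}")
        if (df["count"] < 0).any():
            raise ValueError("endoleak counts must be non-negative")
        self.df = df.copy()
        self.patients = sorted(df["patient_id"].unique())
        for tech in self.techniques:
            sub = df[df["tech"] == tech]
            for (obs, rd), grp in sub.groupby(["observer", "reading"]):
                if sorted(grp["patient_id"]) != self.patients:
                    raise ValueError(
                        f"technique {tech}, session {obs}{rd}: incomplete patient set")

    @property
    def techniques(self) -> list[str]:
        return sorted(self.df["tech"].unique())

    @classmethod
    def from_csv(cls, path: str | Path) -> "ReaderTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    def ratings(self, tech: str, observer: str, reading: int) -> np.ndarray:
        sub = self.df[(self.df["tech"] == tech) & (self.df["observer"] == observer)
                      & (self.df["reading"] == reading)]
        if sub.empty:
            raise KeyError(f"no session ({tech}, {observer}, {reading}) in table")
        return (sub.set_index("patient_id").loc[self.patients, "count"]
                .to_numpy(dtype=int))

    def reference(self) -> np.ndarray:
        return self.ratings(self.REFERENCE_TECH, "ref", 1)

    def sessions(self, tech: str) -> list[tuple[str, int]]:
        sub = self.df[self.df["tech"] == tech]
        return sorted({(o, int(r)) for o, r in zip(sub["observer"], sub["reading"])})


def consensus_counts(table: ReaderTable, technique: str) -> tuple[np.ndarray, int]:
    """Majority count per patient across that technique's reading sessions.

    Ties are broken toward the reference-standard count when it is among the
    tied values, otherwise toward the lower count.  Returns (per-patient
    counts in patient order, total)."""
    sessions = table.sessions(technique)
    votes = np.stack([table.ratings(technique, o, r) for o, r in sessions])
    ref = table.reference()
    out = np.empty(len(table.patients), dtype=int)
    for j in range(votes.shape[1]):
        vals, cnts = np.unique(votes[:, j], return_counts=True)
        best = vals[cnts == cnts.max()]
        out[j] = ref[j] if ref[j] in best else int(best.min())
    return out, int(out.sum())


def _data_path(name: str) -> Path:
    return Path(str(_res_files("dynaleak.data").joinpath(name)))


def load_reader_table() -> ReaderTable:
    """The packaged per-patient endoleak count table (19 patients; dCTA and
    dCTP each read twice by two observers, plus the triphasic reference)."""
    return ReaderTable.from_csv(_data_path("reader_counts.csv"))


def load_dose_table() -> pd.DataFrame:
    """Packaged median DLP per scan phase (mGy*cm), with effective doses."""
    df = pd.read_csv(_data_path("dose_dlp.csv"))
    df["effective_dose_msv"] = df["dlp_mgycm"].map(effective_dose)
    return df
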