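"""Reader-agreement statistics: Cohen's and Fleiss' kappa, paired tests.

Agreement between readers (or between a simulated and a conventional
radiograph read by the same reader) is summarized by chance-corrected
kappa statistics: Cohen's kappa for two raters,

    kappa = (p_o - p_e) / (1 - p_e),

with ``p_o`` the observed proportion of exact agreement and ``p_e`` the
chance agreement expected from the two raters' marginal rating
frequencies, and Fleiss' kappa for repeated readings treated as
interchangeable raters. Confidence intervals come from a seeded
nonparametric bootstrap over items (percentile method, clipped to
[-1, 1]) — appropriate for the small ordinal tables reader studies
produce, and naturally yielding intervals that end at 1.00 when the
estimate is near-perfect.

Kappa values are interpreted on the conventional bands: poor (<= 0),
slight (0-0.2], fair (0.2-0.4], moderate (0.4-0.6], substantial
(0.6-0.8], perfect (0.8-1.0].

Unweighted kappa is the default; linear and quadratic weighting are
available for ordinal scales. ``simulate_ratings`` generates two-rater
tables from a copy model whose expected kappa equals the copy
probability, enabling parameter-recovery checks of the whole chain.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar

from .errors import ParameterError, SampleSizeError, ValidationError

INTERPRETATION_BANDS = (
    (0.0, "poor"),
    (0.2, "slight"),
    (0.4, "fair"),
    (0.6, "moderate"),
    (0.8, "substantial"),
    (1.0, "perfect"),
)


@dataclass
class RatingTable:
    """Items x raters ordinal codes; ``np.nan`` marks a missing rating."""

    ratings: np.ndarray
    items: list
    raters: list
    scale: list

    def __post_init__(self):
        self.ratings = np.asarray(self.ratings, dtype=np.float64)
        if self.ratings.ndim != 2:
            raise ValidationError("ratings must be a 2D items x raters grid")
        n, r = self.ratings.shape
        if n < 2 or r < 2:
            raise SampleSizeError(f"need >= 2 items and >= 2 raters, got {n} x {r}")
        if len(self.items) != n or len(self.raters) != r:
            raise ValidationError("items/raters labels do not match the ratings grid")
        scale = np.asarray(self.scale, dtype=np.float64)
        if scale.size < 2 or np.any(np.diff(scale) <= 0):
            raise ValidationError(f"scale must be strictly increasing with >= 2 codes, got {self.scale}")
        present = self.ratings[~np.isnan(self.ratings)]
        if not np.all(np.isin(present, scale)):
            bad = sorted(set(present.tolist()) - set(scale.tolist()))
            raise ValidationError(f"ratings outside the declared scale: {bad}")

    @classmethod
    def from_arrays(cls, *columns, scale=None, raters=None) -> "RatingTable":
        """Build a table from per-rater rating sequences."""
        arr = np.column_stack([np.asarray(c, dtype=np.float64) for c in columns])
        if scale is None:
            scale = sorted(set(arr[~np.isnan(arr)].tolist()))
        if raters is None:
            raters = [f"rater{i + 1}" for i in range(arr.shape[1])]
        return cls(arr, list(range(1, arr.shape[0] + 1)), list(raters), list(scale))

    @classmethod
    def from_csv(cls, path) -> "RatingTable":
        """Read items x raters CSV: header of rater IDs, first column item
        IDs, optional leading ``# scale=...`` comment line."""
        text = Path(path).read_text()
        scale = None
        lines = []
        for line in text.splitlines():
            if line.startswith("#"):
                body = line.lstrip("# ").strip()
                if body.startswith("scale="):
                    scale = [float(x) for x in body[len("scale="):].split(",")]
            else:
                lines.append(line)
        df = pd.read_csv(io.StringIO("\n".join(lines)), index_col=0)
        arr = df.to_numpy(dtype=np.float64)
        if scale is None:
            scale = sorted(set(arr[~np.isnan(arr)].tolist()))
        return cls(arr, df.index.tolist(), df.columns.tolist(), scale)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.ratings, index=self.items, columns=self.raters)
        df.index.name = "item"
        scale_txt = ",".join(f"{s:g}" for s in self.scale)
        Path(path).write_text(f"# scale={scale_txt}\n" + df.to_csv())


@dataclass
class KappaResult:
    """A kappa estimate with bootstrap CI and interpretation label."""

    estimate: float
    ci_low: float
    ci_high: float
    method: str
    n_items: int
    interpretation: str

    def __post_init__(self):
        if not (self.ci_low <= self.estimate + 1e-12 and self.estimate - 1e-12 <= self.ci_high):
            raise ValidationError(
                f"CI [{self.ci_low}, {self.ci_high}] does not bracket the estimate {self.estimate}"
            )


def interpret_kappa(k: float) -> str:
    """Interpretation label for a kappa value; band edges are upper-closed."""
    if not (-1.0 - 1e-12 <= k <= 1.0 + 1e-12):
        raise ParameterError(f"kappa must be in [-1, 1], got {k}")
    for upper, label in INTERPRETATION_BANDS:
        if k <= upper + 1e-12:
            return label
    return "perfect"


def _weight_matrix(k: int, weights: str | None) -> np.ndarray | None:
    if weights is None:
        return None
    idx = np.arange(k, dtype=np.float64)
    diff = np.abs(idx[:, None] - idx[None, :]) / max(k - 1, 1)
    if weights == "linear":
        return 1.0 - diff
    if weights == "quadratic":
        return 1.0 - diff**2
    raise ParameterError(f"unknown weighting {weights!r}")


def _cohen_from_counts(counts: np.ndarray, w: np.ndarray | None) -> np.ndarray:
    """Kappa from (B, K, K) contingency counts, vectorized over axis 0."""
    n = counts.sum(axis=(1, 2), keepdims=True)
    p = counts / n
    m1 = p.sum(axis=2)
    m2 = p.sum(axis=1)
    if w is None:
        po = np.einsum("bkk->b", p)
        pe = np.einsum("bk,bk->b", m1, m2)
    else:
        po = np.einsum("bij,ij->b", p, w)
        pe = np.einsum("bi,bj,ij->b", m1, m2, w)
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = (po - pe) / (1.0 - pe)
    return np.where(np.isclose(pe, 1.0), 1.0, kappa)


def _complete_pairs(t: RatingTable) -> tuple[np.ndarray, np.ndarray, int]:
    if t.ratings.shape[1] != 2:
        raise ValidationError(f"Cohen's kappa needs exactly 2 raters, got {t.ratings.shape[1]}")
    keep = ~np.isnan(t.ratings).any(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        warnings.warn(f"dropped {dropped} item(s) with a missing rating")
    rat = t.ratings[keep]
    if rat.shape[0] < 2:
        raise SampleSizeError("need >= 2 items with both ratings present")
    scale = np.asarray(t.scale, dtype=np.float64)
    a = np.searchsorted(scale, rat[:, 0])
    b = np.searchsorted(scale, rat[:, 1])
    return a.astype(np.int64), b.astype(np.int64), len(scale)


def cohen_kappa(
    t: RatingTable,
    n_boot: int = 2000,
    seed: int = 0,
    weights: str | None = None,
    ci_level: float = 0.95,
) -> KappaResult:
    """Cohen's kappa for a two-rater table, with bootstrap CI.

    Items with a missing rating are dropped (pairwise deletion). When both
    raters give a single identical rating throughout, chance agreement is
    1 and kappa is defined as 1 with a degenerate-CI warning.
    """
    a, b, k = _complete_pairs(t)
    n = len(a)
    w = _weight_matrix(k, weights)
    pair = a * k + b
    base = np.bincount(pair, minlength=k * k).reshape(1, k, k).astype(np.float64)
    po_pe_degenerate = np.isclose(_chance_agreement(base[0]), 1.0)
    est = float(_cohen_from_counts(base, w)[0])
    if po_pe_degenerate:
        warnings.warn("both raters constant and identical: kappa defined as 1, CI degenerate")
    lo, hi = _bootstrap_ci_pairs(pair, k, w, est, n_boot, seed, ci_level)
    method = "cohen" if weights is None else f"cohen-{weights}"
    return KappaResult(est, lo, hi, method, n, interpret_kappa(est))


def _chance_agreement(counts: np.ndarray) -> float:
    p = counts / counts.sum()
    return float(p.sum(axis=1) @ p.sum(axis=0))


def _bootstrap_ci_pairs(pair, k, w, est, n_boot, seed, ci_level):
    if n_boot <= 0:
        return est, est
    n = len(pair)
    rng = np.random.default_rng(seed)
    alpha = (1.0 - ci_level) / 2
    lows, highs = [], []
    # chunk resamples to bound memory at ~4e6 draws per block
    chunk = max(1, int(4e6 // n))
    samples = np.empty(n_boot)
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        idx = rng.integers(0, n, size=(b, n))
        vals = pair[idx]
        flat = (np.arange(b)[:, None] * (k * k) + vals).ravel()
        counts = np.bincount(flat, minlength=b * k * k).reshape(b, k, k).astype(np.float64)
        samples[done:done + b] = _cohen_from_counts(counts, w)
        done += b
    lo, hi = np.quantile(samples, [alpha, 1.0 - alpha])
    return float(np.clip(lo, -1.0, 1.0)), float(np.clip(hi, -1.0, 1.0))


def fleiss_kappa(
    t: RatingTable,
    n_boot: int = 2000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> KappaResult:
    """Fleiss' kappa over an item x category count matrix, bootstrap CI.

    Repeated readings are treated as interchangeable raters; items with
    fewer than 2 ratings are dropped with a warning. All retained items
    must have the same number of ratings.
    """
    scale = np.asarray(t.scale, dtype=np.float64)
    k = len(scale)
    present = ~np.isnan(t.ratings)
    keep = present.sum(axis=1) >= 2
    if not keep.all():
        warnings.warn(f"dropped {int((~keep).sum())} item(s) with fewer than 2 ratings")
    rat = t.ratings[keep]
    if rat.shape[0] < 2:
        raise SampleSizeError("need >= 2 items with >= 2 ratings each")
    per_item = (~np.isnan(rat)).sum(axis=1)
    if len(set(per_item.tolist())) != 1:
        raise ValidationError("Fleiss' kappa needs the same number of ratings per item")
    r = int(per_item[0])
    counts = np.zeros((rat.shape[0], k))
    for j, s in enumerate(scale):
        counts[:, j] = (rat == s).sum(axis=1)
    est = float(_fleiss_from_counts(counts[None, ...], r)[0])
    lo, hi = _bootstrap_ci_fleiss(counts, r, n_boot, seed, ci_level) if n_boot > 0 else (est, est)
    return KappaResult(est, lo, hi, "fleiss", counts.shape[0], interpret_kappa(est))


def _fleiss_from_counts(counts: np.ndarray, r: int) -> np.ndarray:
    """Fleiss' kappa from (B, n, K) count matrices, vectorized over axis 0."""
    n = counts.shape[1]
    p_i = ((counts**2).sum(axis=2) - r) / (r * (r - 1))
    p_bar = p_i.mean(axis=1)
    p_j = counts.sum(axis=1) / (n * r)
    pe = (p_j**2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = (p_bar - pe) / (1.0 - pe)
    return np.where(np.isclose(pe, 1.0), 1.0, kappa)


def _bootstrap_ci_fleiss(counts, r, n_boot, seed, ci_level):
    n = counts.shape[0]
    rng = np.random.default_rng(seed)
    alpha = (1.0 - ci_level) / 2
    chunk = max(1, int(2e6 // n))
    samples = np.empty(n_boot)
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        idx = rng.integers(0, n, size=(b, n))
        samples[done:done + b] = _fleiss_from_counts(counts[idx], r)
        done += b
    lo, hi = np.quantile(samples, [alpha, 1.0 - alpha])
    return float(np.clip(lo, -1.0, 1.0)), float(np.clip(hi, -1.0, 1.0))


@dataclass
class ComparisonResult:
    """Outcome of a paired modality-difference test."""

    test: str
    statistic: float
    p_value: float


def compare_modalities(x, y, kind: str) -> ComparisonResult:
    """Two-sided paired test between modalities, chosen by variable type.

    ``numeric`` -> paired t-test, ``binary`` -> McNemar's chi-square
    (without continuity correction), ``ordinal`` -> Wilcoxon signed-rank
    with zero differences excluded (exact distribution below 25 non-zero
    pairs, normal approximation above).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("paired samples must be equal-length 1D arrays")
    if len(x) < 2:
        raise SampleSizeError(f"need >= 2 pairs, got {len(x)}")
    diffs = x - y
    if kind == "numeric":
        if np.allclose(diffs, 0.0):
            warnings.warn("all paired differences are zero; p-value defined as 1")
            return ComparisonResult("paired-t", 0.0, 1.0)
        if np.ptp(diffs) == 0:
            warnings.warn("constant non-zero differences: paired-t variance is zero")
            return ComparisonResult("paired-t", np.inf, 0.0)
        st, p = stats.ttest_rel(x, y)
        return ComparisonResult("paired-t", float(st), float(p))
    if kind == "binary":
        vals = np.unique(np.concatenate([x, y]))
        if len(vals) > 2:
            raise ValidationError(f"binary comparison needs <= 2 distinct values, got {vals.tolist()}")
        if len(vals) == 1:
            warnings.warn("all values identical; p-value defined as 1")
            return ComparisonResult("mcnemar", 0.0, 1.0)
        a = x == vals[1]
        b = y == vals[1]
        table = np.array(
            [
                [np.sum(a & b), np.sum(a & ~b)],
                [np.sum(~a & b), np.sum(~a & ~b)],
            ]
        )
        if table[0, 1] + table[1, 0] == 0:
            warnings.warn("no discordant pairs; p-value defined as 1")
            return ComparisonResult("mcnemar", 0.0, 1.0)
        res = mcnemar(table, exact=False, correction=False)
        return ComparisonResult("mcnemar", float(res.statistic), float(res.pvalue))
    if kind == "ordinal":
        nz = diffs[diffs != 0]
        if len(nz) == 0:
            warnings.warn("all paired differences are zero; p-value defined as 1")
            return ComparisonResult("wilcoxon", 0.0, 1.0)
        method = "exact" if len(nz) < 25 else "approx"
        st, p = stats.wilcoxon(x, y, zero_method="wilcox", method=method)
        return ComparisonResult("wilcoxon", float(st), float(p))
    raise ParameterError(f"unknown variable kind {kind!r}")


def simulate_ratings(
    n_items: int,
    k_categories: int,
    marginal=None,
    agreement: float = 0.8,
    seed: int = 0,
) -> RatingTable:
    """Two-rater copy-model simulator with expected kappa = ``agreement``.

    Rater 1 draws each item from ``marginal`` (uniform by default); rater
    2 copies rater 1 with probability ``agreement`` and otherwise draws
    independently from the same marginal. Chance-corrected agreement of
    this mixture equals the copy probability exactly, so kappa estimated
    from the simulated table should recover ``agreement``.
    """
    if n_items < 2 or k_categories < 2:
        raise ParameterError("need n_items >= 2 and k_categories >= 2")
    if not (0.0 <= agreement <= 1.0):
        raise ParameterError(f"agreement must be in [0, 1], got {agreement}")
    if marginal is None:
        marginal = np.full(k_categories, 1.0 / k_categories)
    marginal = np.asarray(marginal, dtype=np.float64)
    if marginal.shape != (k_categories,) or np.any(marginal < 0) or not np.isclose(marginal.sum(), 1.0):
        raise ParameterError("marginal must be a probability vector over the categories")
    rng = np.random.default_rng(seed)
    cats = np.arange(1, k_categories + 1, dtype=np.float64)
    r1 = rng.choice(cats, size=n_items, p=marginal)
    indep = rng.choice(cats, size=n_items, p=marginal)
    copy = rng.random(n_items) < agreement
    r2 = np.where(copy, r1, indep)
    return RatingTable.from_arrays(r1, r2, scale=cats.tolist())
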