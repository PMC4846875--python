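"""Signed Kolmogorov–Smirnov profiling statistics.

The quantitative core of the profiling pipeline: each per-cell descriptor
distribution under a compound treatment is compared against the matched
vehicle (DMSO) control with a *signed* two-sample Kolmogorov–Smirnov
statistic, standardized into a Z-score by the bootstrap-estimated standard
deviation of the control-vs-control statistic, filtered for replicate
reliability, and assembled into the compound × (descriptor, time) Z matrix
that feeds the multivariate analysis.

Sign convention (Perlman-style): positive means the treated distribution is
shifted toward *larger* values than control; the magnitude is the ordinary
two-sample KS distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SignedKSResult",
    "NullStd",
    "ReliabilityReport",
    "signed_ks",
    "bootstrap_null_std",
    "z_score",
    "reliability_filter",
    "assemble_z_matrix",
]


@dataclass(frozen=True)
class SignedKSResult:
    """Signed two-sample KS comparison of treated vs control samples.

    Attributes
    ----------
    d_plus : float
        sup_x [F_control(x) - F_treated(x)]; large when treated values are
        stochastically larger than control.
    d_minus : float
        sup_x [F_treated(x) - F_control(x)]; large when treated values are
        stochastically smaller.
    signed_d : float
        +max(d_plus, d_minus) when d_plus >= d_minus (treated shifted up),
        else -max(d_plus, d_minus). Ties resolve to +.
    """

    d_plus: float
    d_minus: float
    signed_d: float
    n_treated: int
    n_control: int


@dataclass(frozen=True)
class NullStd:
    """Bootstrap estimate of the control-vs-control signed-KS spread."""

    std: float
    n_boot: int
    n_control: int
    degenerate: bool
    seed: int | None = None


@dataclass
class ReliabilityReport:
    """Per-column replicate reliability of Z-scores.

    ``table`` has one row per Z-matrix column with the Pearson correlation
    between the two replicate Z vectors (across compounds) and the retained
    flag (r > threshold). Columns with undefined correlation (zero variance
    in either replicate) are dropped and listed in ``dropped_degenerate``.
    """

    table: pd.DataFrame
    threshold: float
    dropped_degenerate: list = field(default_factory=list)

    @property
    def retained(self) -> list:
        return list(self.table.index[self.table["retained"]])


def _as_sample(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} sample is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} sample contains non-finite values")
    return arr


def signed_ks(treated, control) -> SignedKSResult:
    """Signed one-sided two-sample KS statistic of treated vs control.

    Both one-sided suprema are evaluated exactly over the pooled sample
    points; the signed statistic carries the magnitude of the larger one and
    a sign indicating the direction of the distribution shift (+ = treated
    larger). Swapping the samples flips the sign.
    """
    t = np.sort(_as_sample(treated, "treated"))
    c = np.sort(_as_sample(control, "control"))
    xs = np.unique(np.concatenate([t, c]))
    f_t = np.searchsorted(t, xs, side="right") / t.size
    f_c = np.searchsorted(c, xs, side="right") / c.size
    diff = f_c - f_t
    d_plus = float(max(diff.max(), 0.0))
    d_minus = float(max((-diff).max(), 0.0))
    # ties (within float noise) resolve to +, so swapping the samples of a
    # tied comparison yields + in both directions rather than flipping
    signed = d_plus if d_plus >= d_minus - 1e-12 else -d_minus
    return SignedKSResult(d_plus, d_minus, signed, t.size, c.size)


def _signed_ks_from_counts(cnt_t: np.ndarray, cnt_c: np.ndarray) -> np.ndarray:
    """Vectorised signed KS for count representations over shared support.

    ``cnt_t`` is (n_boot, m) counts of the treated-side resamples over the m
    sorted unique control values; ``cnt_c`` is (m,) or (n_boot, m).
    """
    f_t = np.cumsum(cnt_t, axis=1) / cnt_t.sum(axis=1, keepdims=True)
    cc = np.atleast_2d(cnt_c)
    f_c = np.cumsum(cc, axis=1) / cc.sum(axis=1, keepdims=True)
    diff = f_c - f_t
    d_plus = np.maximum(diff.max(axis=1), 0.0)
    d_minus = np.maximum((-diff).max(axis=1), 0.0)
    return np.where(d_plus >= d_minus - 1e-12, d_plus, -d_minus)


def bootstrap_null_std(
    control,
    n_boot: int = 1000,
    seed: int | None = None,
    n_treated: int | None = None,
    mode: str = "pair",
) -> NullStd:
    """Bootstrap SD of the control-vs-control signed-KS statistic.

    For each of ``n_boot`` rounds, draw with replacement from ``control`` and
    compute the signed KS statistic of a null comparison; return the sample
    SD of the ``n_boot`` values. Deterministic given ``seed``.

    Parameters
    ----------
    mode : {"pair", "single"}
        "pair" (default) compares two independent resamples of sizes
        ``n_treated`` and ``len(control)``, mirroring the sampling noise of a
        real treated-vs-control comparison (Z calibrates to SD ~ 1 under the
        null). "single" compares one resample against the original control
        sample; its spread is ~sqrt(2) smaller because resample and
        reference share the same draw.
    """
    c = _as_sample(control, "control")
    if c.size < 2:
        raise ValueError("control sample must have >= 2 values")
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if mode not in ("pair", "single"):
        raise ValueError(f"unknown bootstrap mode: {mode!r}")
    n_t = c.size if n_treated is None else int(n_treated)

    vals, counts = np.unique(c, return_counts=True)
    if vals.size == 1:
        return NullStd(0.0, n_boot, c.size, degenerate=True, seed=seed)
    p = counts / c.size
    rng = np.random.default_rng(seed)
    # A with-replacement resample of size n from the control ECDF is, in
    # distribution, a multinomial(n, p) draw over the unique control values.
    cnt_t = rng.multinomial(n_t, p, size=n_boot)
    if mode == "pair":
        cnt_c = rng.multinomial(c.size, p, size=n_boot)
    else:
        cnt_c = counts
    signed = _signed_ks_from_counts(cnt_t, cnt_c)
    return NullStd(float(np.std(signed, ddof=1)), n_boot, c.size,
                   degenerate=False, seed=seed)


def z_score(treated, control, null_std: NullStd | float) -> float:
    """Standardized Z = signed_KS(treated, control) / null SD.

    A zero / degenerate null SD means the descriptor is uninformative; the
    caller must exclude it rather than divide (raises ValueError here).
    """
    std = null_std.std if isinstance(null_std, NullStd) else float(null_std)
    if not std > 0:
        raise ValueError("null_std must be > 0; degenerate descriptors are "
                         "excluded upstream, not scored")
    return signed_ks(treated, control).signed_d / std


def reliability_filter(
    z_rep1: pd.DataFrame,
    z_rep2: pd.DataFrame,
    threshold: float = 0.4,
) -> ReliabilityReport:
    """Retain Z-matrix columns reproducible across independent replicates.

    ``z_rep1``/``z_rep2`` are compounds × (descriptor, time) Z matrices from
    the two replicate experiments. For each column the Pearson correlation r
    across compounds is computed; the column is retained iff r > threshold.
    Columns where either replicate has zero variance have undefined r and
    are dropped (reported separately).
    """
    if not z_rep1.columns.equals(z_rep2.columns) or not z_rep1.index.equals(z_rep2.index):
        raise ValueError("replicate Z matrices must share compounds and columns")
    a = z_rep1.to_numpy(dtype=float)
    b = z_rep2.to_numpy(dtype=float)
    da = a - a.mean(axis=0)
    db = b - b.mean(axis=0)
    sa = np.sqrt((da * da).sum(axis=0))
    sb = np.sqrt((db * db).sum(axis=0))
    ok = (sa > 0) & (sb > 0)
    r = np.full(a.shape[1], np.nan)
    r[ok] = (da[:, ok] * db[:, ok]).sum(axis=0) / (sa[ok] * sb[ok])
    table = pd.DataFrame(
        {"r": r, "retained": ok & (r > threshold)}, index=z_rep1.columns
    )
    dropped = list(z_rep1.columns[~ok])
    return ReliabilityReport(table=table, threshold=threshold,
                             dropped_degenerate=dropped)


def assemble_z_matrix(
    z_values: pd.DataFrame,
    retained: list,
    compounds: list,
    time_points: list,
    combine: str = "mean",
) -> pd.DataFrame:
    """Assemble the compound × (descriptor, time) Z matrix.

    Parameters
    ----------
    z_values : DataFrame
        Long table with columns ``compound``, ``descriptor``, ``time_min``,
        ``replicate``, ``z``.
    retained : list of (descriptor, time) pairs (or descriptor names, in
        which case all time points of the descriptor are kept).
    combine : {"mean", "concat"}
        How replicate Z-scores enter the matrix: averaged (default) or kept
        as separate ``rep`` column levels.

    Returns
    -------
    DataFrame with rows = compounds, MultiIndex columns (descriptor, time)
    [plus replicate level when concatenating]. Raises on any missing cell.
    """
    required = {"compound", "descriptor", "time_min", "replicate", "z"}
    if not required.issubset(z_values.columns):
        raise ValueError(f"z_values must have columns {sorted(required)}")
    if combine not in ("mean", "concat"):
        raise ValueError(f"unknown combine rule: {combine!r}")

    retained = list(retained)
    if retained and not isinstance(retained[0], tuple):
        retained = [(d, t) for d in retained for t in time_points]
    keep = pd.MultiIndex.from_tuples(retained, names=["descriptor", "time_min"])

    if combine == "mean":
        wide = z_values.pivot_table(
            index="compound", columns=["descriptor", "time_min"], values="z",
            aggfunc="mean",
        )
    else:
        wide = z_values.pivot_table(
            index="compound", columns=["descriptor", "time_min", "replicate"],
            values="z", aggfunc="mean",
        )
        keep = pd.MultiIndex.from_tuples(
            [(d, t, r) for (d, t) in retained
             for r in sorted(z_values["replicate"].unique())],
            names=["descriptor", "time_min", "replicate"],
        )

    missing_cols = [c for c in keep if c not in wide.columns]
    missing_rows = [c for c in compounds if c not in wide.index]
    if missing_cols or missing_rows:
        raise ValueError(
            "incomplete Z coverage: missing rows "
            f"{missing_rows} / columns {missing_cols[:10]}"
        )
    out = wide.loc[list(compounds), keep]
    if out.isna().any().any():
        bad = [
            (row, col)
            for row in out.index
            for col in out.columns[out.loc[row].isna()]
        ]
        raise ValueError(f"missing Z values for {bad[:10]}")
    return out
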