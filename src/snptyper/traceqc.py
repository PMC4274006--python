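"""Trace quality control for Sanger-style reads.

Implements the trace score (TS) / contiguous read length (CRL) quality
model used by capillary-sequencing QC software, the sliding-window end
trimmer, and per-region success-rate reporting.

Definitions
-----------
TS
    Arithmetic mean of the basecall quality values (QV) of the post-trim
    read; 0 for an empty trim.  Quality levels: low 0-20, medium 21-34,
    high 35-100.
CRL
    Length of the longest contiguous stretch of positions whose
    window-smoothed QV exceeds 20 (window 20 bp, centred, shrinking at
    the read ends).  A raw per-base variant is available via
    ``smoothed=False``.
Pass rule
    A trace passes when TS >= 35 and CRL >= 200 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import UsageError
from ._seq import PURE_BASES

TS_PASS_MIN = 35
CRL_PASS_MIN = 200


@dataclass(frozen=True)
class QualityRead:
    """One directional read: bases, per-base QV, per-base secondary-peak
    fraction (second-highest chromatogram peak relative to the first)."""

    read_id: str
    sample_id: str
    locus_id: str
    direction: Literal["forward", "reverse"]
    bases: str
    qv: tuple[int, ...]
    secondary_fraction: tuple[float, ...]

    def __post_init__(self):
        if not (len(self.bases) == len(self.qv) == len(self.secondary_fraction)):
            raise UsageError(f"{self.read_id}: bases/qv/secondary lengths differ")
        if self.qv and not (0 <= min(self.qv) and max(self.qv) <= 60):
            raise UsageError(f"{self.read_id}: QV outside [0, 60]")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class TrimmedRead:
    """Retained interval of a read after end trimming (1-based, inclusive
    on the original read).  ``empty`` marks a read with no acceptable
    interval; ``start``/``end`` are then 0."""

    read: QualityRead
    start_1based: int
    end_1based: int
    empty: bool = False

    @property
    def bases(self) -> str:
        if self.empty:
            return ""
        return self.read.bases[self.start_1based - 1 : self.end_1based]

    @property
    def qv(self) -> tuple[int, ...]:
        if self.empty:
            return ()
        return self.read.qv[self.start_1based - 1 : self.end_1based]

    @property
    def secondary_fraction(self) -> tuple[float, ...]:
        if self.empty:
            return ()
        return self.read.secondary_fraction[self.start_1based - 1 : self.end_1based]

    def __len__(self) -> int:
        return 0 if self.empty else self.end_1based - self.start_1based + 1


@dataclass(frozen=True)
class TraceMetrics:
    read_id: str
    sample_id: str
    locus_id: str
    trace_score: float
    crl: int
    trimmed_length: int
    quality_level: Literal["low", "medium", "high"] = field(init=False)
    passes: bool = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "quality_level", quality_level(self.trace_score))
        object.__setattr__(
            self, "passes", self.trace_score >= TS_PASS_MIN and self.crl >= CRL_PASS_MIN
        )


def quality_level(ts: float) -> Literal["low", "medium", "high"]:
    """Quality level from the rounded trace score (printed intervals
    0-20 / 21-34 / 35-100 are closed integer bands)."""
    r = int(Decimal(ts).quantize(Decimal("1"), rounding=ROUND_HALF_UP))
    if r <= 20:
        return "low"
    if r <= 34:
        return "medium"
    return "high"


def _bad(base: str, q: int, qv_floor: int) -> bool:
    return q < qv_floor or base not in PURE_BASES


def trim_read(
    read: QualityRead, window: int = 25, qv_floor: int = 25, max_bad: int = 3
) -> TrimmedRead:
    """Trim both ends until the terminal window is clean.

    From the 5' end, the start advances one base at a time until the
    window of `window` bases beginning at the candidate start contains
    fewer than `max_bad` bases that are low-quality (QV < `qv_floor`) or
    ambiguous.  The 3' end is then trimmed symmetrically on the
    remaining interval.  Windows shrink when fewer than `window` bases
    remain.  Returns the empty-trim marker when no interval qualifies.
    """
    n = len(read)
    bad = [_bad(b, q, qv_floor) for b, q in zip(read.bases, read.qv)]

    def window_ok(lo: int, hi: int, at_start: bool) -> bool:
        # window inside [lo, hi] (0-based inclusive) anchored at one end;
        # a shrunken window is held to its own length so an all-bad tail
        # can never qualify
        if at_start:
            w = range(lo, min(lo + window, hi + 1))
        else:
            w = range(max(hi - window + 1, lo), hi + 1)
        return sum(bad[i] for i in w) < min(max_bad, len(w))

    start = 0
    while start < n and not window_ok(start, n - 1, at_start=True):
        start += 1
    if start >= n:
        return TrimmedRead(read, 0, 0, empty=True)
    end = n - 1
    while end >= start and not window_ok(start, end, at_start=False):
        end -= 1
    if end < start:
        return TrimmedRead(read, 0, 0, empty=True)
    return TrimmedRead(read, start + 1, end + 1)


def trace_score(trimmed: TrimmedRead) -> float:
    """Mean QV over the retained bases; 0.0 for an empty trim."""
    if trimmed.empty or len(trimmed) == 0:
        return 0.0
    return float(np.mean(trimmed.qv))


def crl(
    read: QualityRead,
    qv_threshold: int = 20,
    window: int = 20,
    smoothed: bool = True,
) -> int:
    """Contiguous read length.

    With ``smoothed=True`` (default) the QV track is first smoothed with
    a centred moving average of `window` bases (shrinking at the edges);
    CRL is the longest run of positions with smoothed QV strictly above
    `qv_threshold`.  ``smoothed=False`` uses raw per-base QVs.
    """
    n = len(read)
    if n == 0:
        return 0
    q = np.asarray(read.qv, dtype=float)
    if smoothed and window > 1:
        half_l = (window - 1) // 2
        half_r = window - 1 - half_l
        csum = np.concatenate(([0.0], np.cumsum(q)))
        idx = np.arange(n)
        lo = np.maximum(idx - half_l, 0)
        hi = np.minimum(idx + half_r, n - 1)
        track = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    else:
        track = q
    above = track > qv_threshold
    best = run = 0
    for flag in above:
        run = run + 1 if flag else 0
        best = max(best, run)
    return int(best)


def trace_metrics(
    read: QualityRead,
    trim_window: int = 25,
    trim_qv: int = 25,
    trim_max_bad: int = 3,
    crl_threshold: int = 20,
    crl_window: int = 20,
) -> TraceMetrics:
    """Trim, score and classify one read."""
    trimmed = trim_read(read, trim_window, trim_qv, trim_max_bad)
    return TraceMetrics(
        read_id=read.read_id,
        sample_id=read.sample_id,
        locus_id=read.locus_id,
        trace_score=trace_score(trimmed),
        crl=crl(read, crl_threshold, crl_window),
        trimmed_length=len(trimmed),
    )


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up, matching how percentages are printed."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def success_rate(metrics: Iterable[TraceMetrics] | Sequence[bool]) -> float:
    """Percent of passing traces, to one decimal (round-half-up).

    Accepts TraceMetrics objects or plain booleans.
    """
    flags = [m.passes if isinstance(m, TraceMetrics) else bool(m) for m in metrics]
    if not flags:
        raise UsageError("success_rate of an empty collection is undefined")
    return round_half_up(100.0 * sum(flags) / len(flags), 1)


def qc_report(metrics: Iterable[TraceMetrics]):
    """Per-region QC summary table (the machine twin of a sequencing
    success/quality table): region, n_traces, pct_pass, mean/min/max TS
    over passing traces, mean trimmed length."""
    import pandas as pd

    rows = []
    by_locus: dict[str, list[TraceMetrics]] = {}
    for m in metrics:
        by_locus.setdefault(m.locus_id, []).append(m)
    for locus, ms in by_locus.items():
        passing = [m for m in ms if m.passes]
        ts_vals = [m.trace_score for m in passing]
        rows.append(
            {
                "region": locus,
                "n_traces": len(ms),
                "n_pass": len(passing),
                "pct_pass": success_rate(ms),
                "mean_ts": round(float(np.mean(ts_vals)), 1) if ts_vals else float("nan"),
                "min_ts": round(float(np.min(ts_vals)), 1) if ts_vals else float("nan"),
                "max_ts": round(float(np.max(ts_vals)), 1) if ts_vals else float("nan"),
                "mean_trimmed_length": (
                    round(float(np.mean([m.trimmed_length for m in passing])), 1)
                    if passing
                    else 0.0
                ),
            }
        )
    return pd.DataFrame(rows)
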