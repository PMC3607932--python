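"""Community dynamics over a profile time series.

Three analyses on consensus TRF profiles collected over time: (1) Bray-Curtis
distance of every profile to the chronologically first one, a stability
trace; (2) identification of observed dual-enzyme TRF combinations against an
in-silico digest database, allowing for the systematic few-base bias between
predicted and observed fragment sizes; (3) Pearson correlation of per-TRF
relative abundances with plant-parameter time series, with t-test
significance stars.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .digest import DigestRecord, DigestStatus
from .trflp import ConsensusProfile, Peak, RawProfile, align_peaks, normalize_profiles

#: Sentinel for a TRF slot outside the sizing window.
OUT_OF_RANGE = "out_of_range"

#: Accepted (predicted - observed) size bias, bases: the prediction runs a
#: few bases long; +-1 base margin for size-calling jitter.
DEFAULT_DRIFT_WINDOW = (3, 7)

#: Conventional significance levels for the star labels.
STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class TRFCombination:
    """An observed (AluI size, RsaI size) pair; a slot may be out of range."""

    alui_size: Union[float, str]
    rsai_size: Union[float, str]


@dataclass
class CorrelationResult:
    """Pearson correlation of one TRF's abundance with one parameter."""

    trf_id: str
    parameter: str
    n: int          # profiles in which the TRF appears (the Observations count)
    n_pairs: int    # paired observations entering the correlation
    r: Optional[float]
    t: Optional[float]
    p: Optional[float]
    stars: str
    flagged: str = ""  # e.g. zero-variance note


@dataclass
class ProfileSeries:
    """Date-ordered, re-aligned and re-normalized profiles for one enzyme.

    ``abundances`` is a date x bin-size table of relative abundances; every
    row sums to 1 (absent TRFs are 0).
    """

    enzyme: str
    abundances: pd.DataFrame


def bray_curtis(p: Sequence[float], q: Sequence[float]) -> float:
    """Bray-Curtis distance in percent: 100 * sum|p-q| / sum(p+q)."""
    pa = np.asarray(p, dtype=float)
    qa = np.asarray(q, dtype=float)
    if pa.shape != qa.shape:
        raise ValueError("vectors must share the bin map")
    if (pa < 0).any() or (qa < 0).any():
        raise ValueError("abundances must be non-negative")
    denom = float(pa.sum() + qa.sum())
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return 100.0 * float(np.abs(pa - qa).sum()) / denom


def build_profile_series(
    dated_profiles: Sequence[tuple],
    enzyme: str,
    gap: float = 1.0,
    floor: float = 50.0,
    min_tf_fraction: float = 0.25,
) -> ProfileSeries:
    """Assemble a time series from dated consensus profiles.

    The consensus profiles are treated as peak lists, re-normalized together
    (same iterative procedure as the replicate pass) and re-aligned onto
    shared bins.  Consensus profiles whose total fluorescence falls below
    ``min_tf_fraction`` of the median are excluded to avoid excessive
    normalization.  Rows are renormalized to relative abundances summing to 1.
    """
    entries = [(pd.Timestamp(d), prof) for d, prof in dated_profiles
               if prof.enzyme == enzyme]
    entries.sort(key=lambda t: t[0])
    if len({d for d, _ in entries}) != len(entries):
        raise ValueError("sample dates must be unique")
    tfs = np.array([prof.total_fluorescence for _, prof in entries])
    median_tf = float(np.median(tfs)) if len(tfs) else 0.0
    kept = [(d, prof) for (d, prof), tf in zip(entries, tfs)
            if tf >= min_tf_fraction * median_tf]
    pseudo = [
        RawProfile(sample_id=str(d.date()), enzyme=enzyme, replicate_id=1,
                   peaks=[Peak(size=s, height=h, area=a) for s, h, a, _ in prof.bins])
        for d, prof in kept
    ]
    normalized, _ = normalize_profiles(pseudo, floor)
    binned = align_peaks(normalized, gap)
    sizes = [round(s, 3) for s in binned[0].bin_sizes] if binned else []
    rows = {}
    for (d, _), bp in zip(kept, binned):
        heights = np.zeros(len(sizes))
        for b, (_s, h, _a) in bp.bins.items():
            heights[b] = h
        total = heights.sum()
        if total == 0:
            continue
        rows[d] = heights / total
    table = pd.DataFrame.from_dict(rows, orient="index", columns=sizes).sort_index()
    return ProfileSeries(enzyme=enzyme, abundances=table)


def distance_to_baseline(series: ProfileSeries) -> list[tuple[pd.Timestamp, float]]:
    """Bray-Curtis distance of every profile to the chronologically first."""
    table = series.abundances
    if len(table) < 2:
        raise ValueError("need at least two profiles")
    baseline = table.iloc[0].to_numpy()
    return [(date, bray_curtis(baseline, row.to_numpy()))
            for date, row in table.iterrows()]


def _slot_matches(pred, observed, window: tuple[int, int]) -> bool:
    if observed == OUT_OF_RANGE:
        return pred.status in (DigestStatus.ND, DigestStatus.OUT_OF_RANGE)
    if pred.status is not DigestStatus.OK:
        return False
    lo, hi = window
    return lo <= pred.length - float(observed) <= hi


def identify_combinations(
    observed: Sequence[TRFCombination],
    digest_db: Sequence[DigestRecord],
    drift_window: tuple[int, int] = DEFAULT_DRIFT_WINDOW,
    enzymes: tuple[str, str] = ("AluI", "RsaI"),
) -> dict[TRFCombination, list[str]]:
    """Candidate taxa for each observed dual-enzyme TRF combination.

    A database sequence is a candidate when, for BOTH enzymes, its predicted
    minus the observed length lies in ``drift_window`` — or, for an observed
    out-of-range slot, its prediction is ND or out of range.  An empty
    candidate list is a valid (unidentified) outcome.
    """
    alui, rsai = enzymes
    result: dict[TRFCombination, list[str]] = {}
    for combo in observed:
        candidates = []
        for rec in digest_db:
            if alui not in rec.entries or rsai not in rec.entries:
                continue
            if _slot_matches(rec.entries[alui], combo.alui_size, drift_window) and \
               _slot_matches(rec.entries[rsai], combo.rsai_size, drift_window):
                candidates.append(rec.taxon or rec.seq_id)
        result[combo] = candidates
    return result


def _stars(p: float) -> str:
    for level, label in STAR_LEVELS:
        if p < level:
            return label
    return ""


def correlate(
    series: ProfileSeries,
    parameters: pd.DataFrame,
    zero_fill: bool = True,
    min_pairs: int = 3,
) -> list[CorrelationResult]:
    """Pearson correlations between TRF abundances and plant parameters.

    For each TRF bin and parameter column, pairs are the dates where a
    profile exists and the parameter is recorded; a TRF absent from an
    existing profile contributes abundance 0 (set ``zero_fill=False`` to drop
    those dates instead).  Significance is the two-sided t-test
    t = r sqrt((n-2)/(1-r^2)) with n-2 degrees of freedom; stars at the
    0.05/0.01/0.001 levels.  ``n`` reports the number of profiles in which
    the TRF appears.
    """
    table = series.abundances
    results = []
    for trf in table.columns:
        abund_all = table[trf]
        n_present = int((abund_all > 0).sum())
        for param in parameters.columns:
            joined = pd.concat([abund_all.rename("a"),
                                parameters[param].rename("x")], axis=1, join="inner")
            joined = joined.dropna(subset=["x"])
            if not zero_fill:
                joined = joined[joined["a"] > 0]
            trf_id = f"{series.enzyme} {trf:g}" if isinstance(trf, float) else f"{series.enzyme} {trf}"
            if len(joined) < min_pairs:
                results.append(CorrelationResult(trf_id, param, n_present,
                                                 len(joined), None, None, None, "",
                                                 flagged="too few pairs"))
                continue
            a = joined["a"].to_numpy(float)
            x = joined["x"].to_numpy(float)
            if np.ptp(a) == 0 or np.ptp(x) == 0:
                results.append(CorrelationResult(trf_id, param, n_present,
                                                 len(joined), None, None, None, "",
                                                 flagged="zero variance"))
                continue
            r, p = stats.pearsonr(a, x)
            dof = len(joined) - 2
            t = r * np.sqrt(dof / (1.0 - r * r)) if abs(r) < 1 else np.inf * np.sign(r)
            results.append(CorrelationResult(trf_id, param, n_present, len(joined),
                                             float(r), float(t), float(p), _stars(p)))
    return results


def correlation_table(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    """Wide table mirroring the published layout: one star/r column per parameter."""
    rows: dict[str, dict] = {}
    for res in results:
        row = rows.setdefault(res.trf_id, {"observations": res.n})
        if res.r is None:
            row[res.parameter] = res.flagged or ""
        else:
            row[res.parameter] = f"{res.r:+.2f}{res.stars}"
    return pd.DataFrame.from_dict(rows, orient="index")
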