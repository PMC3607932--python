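"""Raw electropherogram peaks to consensus TRF relative-abundance profiles.

The fingerprinting workflow: (1) retain peaks within the 50-1020 base sizing
window with height above 50 fluorescence units; (2) keep a sample x enzyme
only if at least two of its replicate profiles carry a total fluorescence
(sum of peak heights, a DNA-load proxy) above 500 FU, and select the top two;
(3) scale the pair to the smaller total fluorescence with sub-threshold peak
removal, iterated to a fixed point (Dunbar-style normalization); (4) align
peaks onto shared size bins by moving-average clustering; (5) combine into a
consensus profile from the bins present in both replicates, averaging size,
height and area; relative abundance is peak height over total fluorescence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sizing window (bases) and detection floor (fluorescence units).
SIZE_MIN, SIZE_MAX = 50.0, 1020.0
HEIGHT_FLOOR = 50.0
#: Replicate quality gate on total fluorescence.
MIN_TOTAL_FLUORESCENCE = 500.0


@dataclass(frozen=True)
class Peak:
    """One detected fragment: called size, peak height and area."""

    size: float
    height: float
    area: float

    def __post_init__(self) -> None:
        if self.height <= 0 or self.size <= 0:
            raise ValueError("peak size and height must be positive")


@dataclass
class RawProfile:
    """One replicate's peak list for one sample x enzyme."""

    sample_id: str
    enzyme: str
    replicate_id: int
    peaks: list[Peak] = field(default_factory=list)

    @property
    def total_fluorescence(self) -> float:
        return float(sum(p.height for p in self.peaks))


@dataclass
class BinnedProfile:
    """A profile mapped onto shared size bins.

    ``bins`` maps bin index -> (size, height, area); ``bin_sizes`` is the
    shared bin-center list (height-weighted mean size of all member peaks).
    """

    sample_id: str
    enzyme: str
    replicate_id: int
    bins: dict[int, tuple[float, float, float]]
    bin_sizes: list[float]

    @property
    def total_fluorescence(self) -> float:
        return float(sum(h for _, h, _ in self.bins.values()))


@dataclass
class ConsensusProfile:
    """Per-sample, per-enzyme TRF profile on aligned bins.

    ``bins`` rows are (bin_size, height, area, relative_abundance), sorted by
    size; relative abundances sum to 1.
    """

    sample_id: str
    enzyme: str
    bins: list[tuple[float, float, float, float]]
    total_fluorescence: float

    @property
    def sizes(self) -> list[float]:
        return [b[0] for b in self.bins]

    @property
    def abundances(self) -> dict[float, float]:
        return {b[0]: b[3] for b in self.bins}


@dataclass
class SelectionResult:
    """Outcome of the replicate quality gate."""

    selected: Optional[tuple[RawProfile, RawProfile]]
    rejected: bool
    reason: str = ""


def filter_peaks(profile: RawProfile,
                 size_window: tuple[float, float] = (SIZE_MIN, SIZE_MAX),
                 floor: float = HEIGHT_FLOOR) -> RawProfile:
    """Retain peaks inside the sizing window with height strictly above floor."""
    lo, hi = size_window
    kept = [p for p in profile.peaks if lo <= p.size <= hi and p.height > floor]
    return replace(profile, peaks=kept)


def select_replicates(replicates: Sequence[RawProfile],
                      min_tf: float = MIN_TOTAL_FLUORESCENCE) -> SelectionResult:
    """Pick the two highest-total-fluorescence replicates, or reject.

    A sample x enzyme passes only if at least two replicates exceed ``min_tf``
    total fluorescence.  Ties are resolved toward the lower replicate id.
    """
    if not 1 <= len(replicates) <= 3:
        raise ValueError("expected 1-3 replicates")
    passing = [r for r in replicates if r.total_fluorescence > min_tf]
    if len(passing) < 2:
        return SelectionResult(None, True,
                               f"only {len(passing)} replicate(s) above {min_tf} FU")
    ranked = sorted(passing, key=lambda r: (-r.total_fluorescence, r.replicate_id))
    return SelectionResult((ranked[0], ranked[1]), False)


def align_peaks(profiles: Sequence[RawProfile], gap: float = 1.0) -> list[BinnedProfile]:
    """Map pooled peaks onto shared size bins by moving-average clustering.

    All peaks are pooled and sorted by size; a peak joins the current bin if
    its size is within ``gap`` of the running mean of the bin's members, else
    it starts a new bin.  Within one profile, multiple peaks falling in a bin
    are summed (heights and areas) with a height-weighted mean size.
    """
    if gap <= 0:
        raise ValueError("gap must be positive")
    pooled = sorted(
        ((peak.size, k, peak) for k, prof in enumerate(profiles) for peak in prof.peaks),
        key=lambda t: t[0],
    )
    bins: list[list[tuple[int, Peak]]] = []
    running_mean = None
    count = 0
    for size, k, peak in pooled:
        if running_mean is None or size - running_mean > gap:
            bins.append([])
            running_mean, count = size, 1
        else:
            count += 1
            running_mean += (size - running_mean) / count
        bins[-1].append((k, peak))

    bin_sizes = []
    for members in bins:
        heights = np.array([p.height for _, p in members])
        sizes = np.array([p.size for _, p in members])
        bin_sizes.append(float(np.average(sizes, weights=heights)))

    out = []
    for k, prof in enumerate(profiles):
        prof_bins: dict[int, tuple[float, float, float]] = {}
        for b, members in enumerate(bins):
            mine = [p for kk, p in members if kk == k]
            if not mine:
                continue
            h = sum(p.height for p in mine)
            a = sum(p.area for p in mine)
            s = sum(p.size * p.height for p in mine) / h
            prof_bins[b] = (s, h, a)
        out.append(BinnedProfile(prof.sample_id, prof.enzyme, prof.replicate_id,
                                 prof_bins, bin_sizes))
    return out


def normalize_profiles(profiles: Sequence[RawProfile],
                       floor: float = HEIGHT_FLOOR
                       ) -> tuple[list[RawProfile], list[float]]:
    """Iterative down-scaling to the smallest total fluorescence.

    Every profile is scaled by (min TF / its TF); scaled peaks at or below
    ``floor`` are deleted (they would be indistinguishable from noise);
    repeat until no deletion occurs.  Returns the normalized profiles and,
    per profile, the fraction of its original total fluorescence removed.
    A profile losing all peaks is returned empty (flag downstream).
    """
    if not profiles:
        raise ValueError("no profiles to normalize")
    # Track original height per peak so removed fractions refer to the input.
    work = [[(p, p.height, p.area) for p in prof.peaks] for prof in profiles]
    original_tf = [sum(orig for _, orig, _ in peaks) for peaks in work]
    removed = [0.0] * len(profiles)

    heights = [[h for (pk, h, a) in peaks] for peaks in work]
    areas = [[a for (pk, h, a) in peaks] for peaks in work]
    while True:
        tfs = [sum(h) for h in heights]
        nonempty = [tf for tf in tfs if tf > 0]
        if not nonempty:
            break
        min_tf = min(nonempty)
        deleted = False
        for i in range(len(work)):
            if tfs[i] <= 0:
                continue
            scale = min_tf / tfs[i]
            heights[i] = [h * scale for h in heights[i]]
            areas[i] = [a * scale for a in areas[i]]
            keep = [j for j, h in enumerate(heights[i]) if h > floor]
            if len(keep) != len(heights[i]):
                deleted = True
                dropped = set(range(len(heights[i]))) - set(keep)
                removed[i] += sum(work[i][j][1] for j in dropped)
                work[i] = [work[i][j] for j in keep]
                heights[i] = [heights[i][j] for j in keep]
                areas[i] = [areas[i][j] for j in keep]
        if not deleted:
            break

    out = []
    fractions = []
    for i, prof in enumerate(profiles):
        peaks = [
            Peak(size=work[i][j][0].size, height=heights[i][j], area=areas[i][j])
            for j in range(len(work[i]))
        ]
        out.append(replace(prof, peaks=peaks))
        fractions.append(removed[i] / original_tf[i] if original_tf[i] > 0 else 0.0)
        if not peaks:
            logger.warning("profile %s/%s rep %s lost all peaks in normalization",
                           prof.sample_id, prof.enzyme, prof.replicate_id)
    return out, fractions


def consensus(profile_a: BinnedProfile, profile_b: BinnedProfile) -> ConsensusProfile:
    """Combine two aligned replicates into a consensus profile.

    Only bins occupied in both replicates survive; per bin, size, height and
    area are arithmetic means; relative abundance is the mean height over the
    consensus total fluorescence.  Zero shared bins yields an (empty-flagged)
    consensus with no bins.
    """
    shared = sorted(set(profile_a.bins) & set(profile_b.bins))
    rows = []
    for b in shared:
        sa, ha, aa = profile_a.bins[b]
        sb, hb, ab = profile_b.bins[b]
        rows.append(((sa + sb) / 2.0, (ha + hb) / 2.0, (aa + ab) / 2.0))
    total = sum(h for _, h, _ in rows)
    if not rows:
        logger.warning("empty consensus for %s/%s", profile_a.sample_id, profile_a.enzyme)
        return ConsensusProfile(profile_a.sample_id, profile_a.enzyme, [], 0.0)
    bins = [(s, h, a, h / total) for s, h, a in sorted(rows)]
    return ConsensusProfile(profile_a.sample_id, profile_a.enzyme, bins, total)


def read_peak_table(path) -> list[RawProfile]:
    """Read the peak-table CSV dialect into raw profiles.

    Columns: sample_id,enzyme,replicate,size_bases,height_fu,area.  A
    malformed row raises a parse error naming the row.
    """
    df = pd.read_csv(path)
    required = ["sample_id", "enzyme", "replicate", "size_bases", "height_fu", "area"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"peak table missing columns: {missing}")
    profiles: dict[tuple, RawProfile] = {}
    for idx, row in df.iterrows():
        try:
            key = (str(row["sample_id"]), str(row["enzyme"]), int(row["replicate"]))
            peak = Peak(size=float(row["size_bases"]), height=float(row["height_fu"]),
                        area=float(row["area"]))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed peak table row {idx}: {exc}") from exc
        profiles.setdefault(key, RawProfile(*key)).peaks.append(peak)
    for prof in profiles.values():
        prof.peaks.sort(key=lambda p: p.size)
    return [profiles[k] for k in sorted(profiles)]


def run_pipeline(
    peak_table,
    gap: float = 1.0,
    floor: float = HEIGHT_FLOOR,
    min_tf: float = MIN_TOTAL_FLUORESCENCE,
    size_window: tuple[float, float] = (SIZE_MIN, SIZE_MAX),
) -> tuple[list[ConsensusProfile], dict]:
    """Full pipeline: filter, replicate QC, normalize, align, consensus.

    ``peak_table`` is a CSV path or a pre-loaded list of raw profiles.
    Returns the per-sample consensus profiles and a QC report (rejected
    samples, removed-fluorescence fractions, empty consensi).
    """
    if isinstance(peak_table, (str, bytes)) or hasattr(peak_table, "__fspath__"):
        raw = read_peak_table(peak_table)
    else:
        raw = list(peak_table)
    groups: dict[tuple[str, str], list[RawProfile]] = {}
    for prof in raw:
        groups.setdefault((prof.sample_id, prof.enzyme), []).append(prof)

    consensi: list[ConsensusProfile] = []
    qc = {"n_samples": len(groups), "rejected": [], "removed_fraction": {},
          "empty_consensus": []}
    for key in sorted(groups):
        replicates = [filter_peaks(p, size_window, floor)
                      for p in sorted(groups[key], key=lambda p: p.replicate_id)]
        sel = select_replicates(replicates, min_tf)
        if sel.rejected:
            qc["rejected"].append({"sample_id": key[0], "enzyme": key[1],
                                   "reason": sel.reason})
            continue
        pair, fractions = normalize_profiles(list(sel.selected), floor)
        qc["removed_fraction"]["%s/%s" % key] = fractions
        binned = align_peaks(pair, gap)
        cons = consensus(binned[0], binned[1])
        if not cons.bins:
            qc["empty_consensus"].append("%s/%s" % key)
            continue
        consensi.append(cons)
    return consensi, qc


def write_consensus_table(profiles: Sequence[ConsensusProfile], path) -> None:
    """Write consensus profiles as CSV: sample_id,enzyme,bin_size,height,area,rel_abundance."""
    rows = [
        {"sample_id": p.sample_id, "enzyme": p.enzyme, "bin_size": s,
         "height": h, "area": a, "rel_abundance": r}
        for p in profiles
        for s, h, a, r in p.bins
    ]
    pd.DataFrame(rows, columns=["sample_id", "enzyme", "bin_size", "height",
                                "area", "rel_abundance"]).to_csv(path, index=False)
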