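"""Sweep-line detection of copy-number-variable regions (sub-CNVRs).

The detector walks each chromosome once.  Every CNV call contributes a
``+1`` event at its start position and a ``-1`` event at its end position;
all events sharing a physical position are applied before any segment is
evaluated, so a call covers the half-open span ``[start_pos, end_pos)`` at
segment granularity.  Between each pair of consecutive distinct event
positions the carrier count is constant; each such inter-SNP segment whose
carrier fraction strictly exceeds the frequency threshold is reported as one
sub-CNVR, bounded by its bracketing SNP positions (reported as a 1-based
closed interval whose end is the position closing the segment).

Because frequency is defined as the *percentage of subjects* with a CNV
inside the boundaries, a preprocessing pass merges each subject's
overlapping same-chromosome calls into maximal covering intervals so the
counter counts subjects, never duplicate calls.

The extended algorithm (:func:`merge_sub_cnvrs`) fuses consecutive
above-threshold sub-CNVRs that share a bracketing position into one larger
region; a subject's state in such a region is no longer unique, so
:func:`assign_states` applies the longest-overlap rule with a second
threshold: the subject's longest-overlapping CNV sets the state iff its
overlap exceeds the stated fraction of the region length (strictly).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .errors import ConfigError, ContractError, ResolutionError
from .io_formats import CnvCall, SnpMarker, chromosome_sort_key

__all__ = [
    "DetectionConfig",
    "SubCnvr",
    "Cnvr",
    "CnvrStateMatrix",
    "filter_min_snps",
    "detect_sub_cnvrs",
    "merge_sub_cnvrs",
    "assign_states",
    "build_state_matrix",
    "coverage_profile",
    "detect_regions",
]


@dataclass
class DetectionConfig:
    """Tuning knobs for region detection.

    freq_threshold
        Minimum carrier fraction (strict ``>``) for a segment to be reported.
    min_snps
        CNV calls spanning fewer probes than this are discarded up front.
    merge
        Run the extended algorithm (merge consecutive sub-CNVRs).
    state_len_threshold
        Longest-overlap fraction (strict ``>``) a subject's CNV must cover of
        a region before its state is used; below it the state is 0.
    pool_states
        Count gains and losses together (default); when false, losses and
        gains are detected as separate region sets.
    absolute_len_threshold
        Optional alternative to ``state_len_threshold``: qualify a CNV by
        absolute overlap in bp instead of a fraction of the region length.
    """

    freq_threshold: float
    min_snps: int = 1
    merge: bool = False
    state_len_threshold: float = 0.5
    pool_states: bool = True
    absolute_len_threshold: Optional[int] = None

    def __post_init__(self):
        if not 0.0 < self.freq_threshold < 1.0:
            raise ConfigError(f"freq_threshold must be in (0,1), got {self.freq_threshold}")
        if self.min_snps < 1:
            raise ConfigError(f"min_snps must be >= 1, got {self.min_snps}")
        if not 0.0 < self.state_len_threshold <= 1.0:
            raise ConfigError(
                f"state_len_threshold must be in (0,1], got {self.state_len_threshold}"
            )
        if self.absolute_len_threshold is not None and self.absolute_len_threshold < 0:
            raise ConfigError("absolute_len_threshold must be >= 0")


@dataclass
class SubCnvr:
    """A detected sub-CNVR: one above-threshold inter-SNP segment.

    Boundaries are approximated by the physical positions of the bracketing
    SNPs; ``frequency`` is exactly ``n_carriers / n_subjects``.
    """

    chromosome: str
    start_pos: int
    end_pos: int
    n_subjects: int
    carrier_ids: frozenset
    n_carriers: Optional[int] = None
    sign: Optional[str] = None  # "loss"/"gain" when detection was unpooled
    start_marker: Optional[str] = None
    end_marker: Optional[str] = None

    def __post_init__(self):
        if self.n_carriers is None:
            self.n_carriers = len(self.carrier_ids)
        if self.start_pos >= self.end_pos:
            raise ContractError(
                f"sub-CNVR {self.chromosome}:{self.start_pos}-{self.end_pos}: "
                "start must be < end"
            )
        if self.n_subjects < 1:
            raise ContractError("n_subjects must be >= 1")

    @property
    def frequency(self) -> float:
        return self.n_carriers / self.n_subjects

    @property
    def region_length(self) -> int:
        return self.end_pos - self.start_pos + 1

    @property
    def region_id(self) -> str:
        base = f"{self.chromosome}:{self.start_pos}-{self.end_pos}"
        return f"{base}:{self.sign}" if self.sign else base


@dataclass
class Cnvr:
    """A merged region: consecutive sub-CNVRs fused into one span.

    The carrier set (hence frequency) is recomputed over the merged span as
    the union of member carriers; member sub-CNVRs retain their own
    frequencies.
    """

    chromosome: str
    start_pos: int
    end_pos: int
    members: list
    n_subjects: int
    carrier_ids: frozenset
    sign: Optional[str] = None

    @property
    def n_carriers(self) -> int:
        return len(self.carrier_ids)

    @property
    def frequency(self) -> float:
        return self.n_carriers / self.n_subjects

    @property
    def region_length(self) -> int:
        return self.end_pos - self.start_pos + 1

    @property
    def region_id(self) -> str:
        base = f"{self.chromosome}:{self.start_pos}-{self.end_pos}"
        return f"{base}:{self.sign}" if self.sign else base


Region = Union[SubCnvr, Cnvr]


@dataclass
class CnvrStateMatrix:
    """Per-subject signed state per region (0 = no qualifying CNV).

    ``frame`` is regions × subjects; row order matches ``regions``.
    """

    frame: pd.DataFrame
    regions: list

    @property
    def region_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.frame.columns)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def filter_min_snps(calls: Sequence[CnvCall], min_snps: int) -> list[CnvCall]:
    """Drop calls spanning strictly fewer probes than ``min_snps``.

    Calls whose marker count is unknown are kept (fail-open on metadata).
    Order is preserved.
    """
    if min_snps < 1:
        raise ConfigError(f"min_snps must be >= 1, got {min_snps}")
    return [c for c in calls if c.n_snps is None or c.n_snps >= min_snps]


# ---------------------------------------------------------------------------
# Sweep line
# ---------------------------------------------------------------------------


def _merged_subject_intervals(calls: Iterable[CnvCall]):
    """Per chromosome, merge each subject's overlapping calls into maximal
    covering intervals (state dropped: these intervals exist only so the
    counter counts subjects)."""
    per_subject = defaultdict(list)  # (chrom, subject) -> [(start, end)]
    for c in calls:
        per_subject[(c.chromosome, c.subject_id)].append((c.start_pos, c.end_pos))
    by_chrom = defaultdict(list)  # chrom -> [(start, end, subject)]
    for (chrom, subject), ivals in per_subject.items():
        ivals.sort()
        cur_s, cur_e = ivals[0]
        for s, e in ivals[1:]:
            if s <= cur_e:  # overlap incl. a shared endpoint
                cur_e = max(cur_e, e)
            else:
                by_chrom[chrom].append((cur_s, cur_e, subject))
                cur_s, cur_e = s, e
        by_chrom[chrom].append((cur_s, cur_e, subject))
    return by_chrom


def _sweep_segments(intervals, extra_positions=()):
    """Yield (seg_start, seg_end, active_subject_set_snapshot) for every
    segment between consecutive distinct event positions on one chromosome.

    ``extra_positions`` lets callers keep a segment boundary at every raw
    call border even where per-subject interval merging removed the event:
    deduplication changes counts, never boundaries.
    """
    starts = defaultdict(list)
    ends = defaultdict(list)
    positions = set(extra_positions)
    for s, e, subject in intervals:
        starts[s].append(subject)
        ends[e].append(subject)
        positions.update((s, e))
    ordered = sorted(positions)
    active: set = set()
    for i, p in enumerate(ordered):
        for subject in starts.get(p, ()):
            active.add(subject)
        for subject in ends.get(p, ()):
            active.discard(subject)
        if i + 1 < len(ordered):
            yield p, ordered[i + 1], active


def _detect_one_pool(calls, n_subjects, cfg, marker_at, sign):
    regions = []
    by_chrom = _merged_subject_intervals(calls)
    borders = defaultdict(set)  # every raw call border remains a segment boundary
    for c in calls:
        borders[c.chromosome].update((c.start_pos, c.end_pos))
    for chrom in sorted(by_chrom, key=chromosome_sort_key):
        if marker_at is not None and chrom not in marker_at:
            raise ResolutionError(f"chromosome {chrom!r} absent from the SNP map")
        lookup = marker_at.get(chrom, {}) if marker_at is not None else {}
        for seg_start, seg_end, active in _sweep_segments(by_chrom[chrom], borders[chrom]):
            if active and len(active) / n_subjects > cfg.freq_threshold:
                regions.append(
                    SubCnvr(
                        chromosome=chrom,
                        start_pos=seg_start,
                        end_pos=seg_end,
                        n_subjects=n_subjects,
                        carrier_ids=frozenset(active),
                        sign=sign,
                        start_marker=lookup.get(seg_start),
                        end_marker=lookup.get(seg_end),
                    )
                )
    return regions


def detect_sub_cnvrs(
    calls: Sequence[CnvCall],
    n_subjects: int,
    cfg: DetectionConfig,
    snp_map: Optional[Sequence[SnpMarker]] = None,
) -> list[SubCnvr]:
    """Run the sweep-line detector and return sub-CNVRs sorted by position.

    ``n_subjects`` is the cohort size (the frequency denominator), which may
    exceed the number of subjects with calls.  When ``snp_map`` is supplied,
    bracketing SNP names are attached and calls on unmapped chromosomes
    raise a :class:`ResolutionError`.
    """
    if n_subjects < 1:
        raise ConfigError(f"n_subjects must be >= 1, got {n_subjects}")
    marker_at = None
    if snp_map is not None:
        marker_at = defaultdict(dict)
        for m in snp_map:
            marker_at[m.chromosome][m.position] = m.marker_id
        marker_at = dict(marker_at)
    if cfg.pool_states:
        regions = _detect_one_pool(calls, n_subjects, cfg, marker_at, None)
    else:
        losses = [c for c in calls if c.state < 0]
        gains = [c for c in calls if c.state > 0]
        regions = _detect_one_pool(losses, n_subjects, cfg, marker_at, "loss")
        regions += _detect_one_pool(gains, n_subjects, cfg, marker_at, "gain")
    regions.sort(key=lambda r: (chromosome_sort_key(r.chromosome), r.start_pos, r.sign or ""))
    return regions


def coverage_profile(calls: Sequence[CnvCall], chromosome: str):
    """Piecewise-constant carrier counts along one chromosome.

    Returns ``[(seg_start, seg_end, n_carriers), ...]`` over all segments
    between consecutive distinct event positions (zero-count gaps included).
    Coverage is measured on half-open spans with per-subject deduplication,
    so ``sum(count * (end - start))`` equals the total covered length.
    """
    on_chrom = [c for c in calls if c.chromosome == chromosome]
    by_chrom = _merged_subject_intervals(on_chrom)
    if chromosome not in by_chrom:
        return []
    borders = {p for c in on_chrom for p in (c.start_pos, c.end_pos)}
    return [
        (seg_start, seg_end, len(active))
        for seg_start, seg_end, active in _sweep_segments(by_chrom[chromosome], borders)
    ]


# ---------------------------------------------------------------------------
# Extended algorithm: merging and state assignment
# ---------------------------------------------------------------------------


def merge_sub_cnvrs(sub_cnvrs: Sequence[SubCnvr]) -> list[Cnvr]:
    """Fuse consecutive sub-CNVRs sharing a bracketing position into regions.

    Input must be the sorted output of :func:`detect_sub_cnvrs`; every input
    sub-CNVR becomes a member of exactly one output region.  Two sub-CNVRs
    merge iff they sit on the same chromosome (and the same detection pool)
    and the first one's end equals the second one's start — i.e. no
    below-threshold segment separates them.
    """
    merged: list[Cnvr] = []
    current: list[SubCnvr] = []

    def flush():
        if current:
            merged.append(
                Cnvr(
                    chromosome=current[0].chromosome,
                    start_pos=current[0].start_pos,
                    end_pos=current[-1].end_pos,
                    members=list(current),
                    n_subjects=current[0].n_subjects,
                    carrier_ids=frozenset().union(*(m.carrier_ids for m in current)),
                    sign=current[0].sign,
                )
            )
            current.clear()

    prev: Optional[SubCnvr] = None
    for r in sub_cnvrs:
        if prev is not None and (r.chromosome, r.sign) == (prev.chromosome, prev.sign):
            if r.start_pos < prev.start_pos:
                raise ContractError("merge_sub_cnvrs requires input sorted by position")
            if r.start_pos < prev.end_pos:
                raise ContractError(
                    f"overlapping sub-CNVRs {prev.region_id} and {r.region_id}; "
                    "input is not detector output"
                )
        if current and (
            r.chromosome == current[-1].chromosome
            and r.sign == current[-1].sign
            and r.start_pos == current[-1].end_pos
        ):
            current.append(r)
        else:
            flush()
            current.append(r)
        prev = r
    flush()
    return merged


def _index_calls(calls: Iterable[CnvCall]):
    idx = defaultdict(list)  # (chrom, subject) -> [calls]
    for c in calls:
        idx[(c.chromosome, c.subject_id)].append(c)
    return idx


def _assign_states_indexed(region: Region, call_index, cfg: DetectionConfig, subjects):
    length = region.region_length
    if length <= 0:
        raise ContractError(f"region {region.region_id}: non-positive length")
    wanted_sign = region.sign
    states = {}
    for subject in subjects:
        best = None
        best_key = None
        for c in call_index.get((region.chromosome, subject), ()):
            if wanted_sign == "loss" and c.state > 0:
                continue
            if wanted_sign == "gain" and c.state < 0:
                continue
            overlap = min(c.end_pos, region.end_pos) - max(c.start_pos, region.start_pos) + 1
            if overlap <= 0:
                continue
            # ties: longest overlap, then larger |state|, then leftmost start
            key = (overlap, abs(c.state), -c.start_pos, c.state)
            if best_key is None or key > best_key:
                best, best_key = c, key
        state = 0
        if best is not None:
            overlap = best_key[0]
            if cfg.absolute_len_threshold is not None:
                qualifies = overlap > cfg.absolute_len_threshold
            else:
                qualifies = overlap / length > cfg.state_len_threshold
            if qualifies:
                state = best.state
        states[subject] = state
    return states


def assign_states(
    region: Region,
    calls: Sequence[CnvCall],
    cfg: DetectionConfig,
    subjects: Sequence[str],
) -> pd.Series:
    """Signed state of every subject in one region (longest-overlap rule).

    Among a subject's CNVs overlapping the region, the one with the longest
    overlap defines the state iff ``overlap / region_length`` strictly
    exceeds ``cfg.state_len_threshold`` (or, with ``absolute_len_threshold``
    set, iff the overlap in bp strictly exceeds it); otherwise the state is 0.
    """
    states = _assign_states_indexed(region, _index_calls(calls), cfg, subjects)
    return pd.Series(states, name=region.region_id).reindex(list(subjects))


def build_state_matrix(
    regions: Sequence[Region],
    calls: Sequence[CnvCall],
    cfg: DetectionConfig,
    subjects: Sequence[str],
) -> CnvrStateMatrix:
    """State matrix (regions × subjects) for the association step."""
    idx = _index_calls(calls)
    subjects = list(subjects)
    rows = {}
    ordered = sorted(
        regions, key=lambda r: (chromosome_sort_key(r.chromosome), r.start_pos, r.sign or "")
    )
    for region in ordered:
        rows[region.region_id] = _assign_states_indexed(region, idx, cfg, subjects)
    frame = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    frame = frame.reindex(columns=subjects)
    frame.index.name = "region_id"
    return CnvrStateMatrix(frame=frame, regions=list(ordered))


def detect_regions(
    calls: Sequence[CnvCall],
    n_subjects: int,
    cfg: DetectionConfig,
    snp_map: Optional[Sequence[SnpMarker]] = None,
) -> list[Region]:
    """Full detection pipeline: min-SNP filter → sweep line → optional merge."""
    filtered = filter_min_snps(calls, cfg.min_snps)
    subs = detect_sub_cnvrs(filtered, n_subjects, cfg, snp_map=snp_map)
    if cfg.merge:
        return merge_sub_cnvrs(subs)
    return list(subs)
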