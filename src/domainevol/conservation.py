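"""Modal-residue conservation profiling and clade-vs-modal contrasts.

Conservation at an aligned site is the percentage of sequences carrying
the modal (most frequent) residue — an identity-to-mode measure, not an
entropy.  Domains (pro, mature, and optional NLS / HCPR sub-regions of
the pro-domain) are defined on a named reference sequence's ungapped
coordinates and projected through its gap pattern onto alignment
columns; columns where the reference is gapped belong to no domain.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .seqio import Alignment

logger = logging.getLogger(__name__)

_GAPLIKE = {"-", "X", "?"}

#: colour-scale annotation bounds used by the heat-map table (metadata only)
HEATMAP_BINS = (25.0, 100.0)


class ConservationError(ValueError):
    pass


@dataclass
class DomainPartition:
    """Named intervals on a reference sequence, 1-based inclusive.

    ``pro`` and ``mature`` must not overlap; ``NLS`` and ``HCPR`` when
    present must lie inside ``pro``.
    """

    reference: str
    intervals: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.intervals.items():
            if not (1 <= lo <= hi):
                raise ConservationError(f"bad interval {name}: [{lo}, {hi}]")
        pro = self.intervals.get("pro")
        mature = self.intervals.get("mature")
        if pro and mature and not (pro[1] < mature[0] or mature[1] < pro[0]):
            raise ConservationError("pro and mature intervals overlap")
        for sub in ("NLS", "HCPR"):
            iv = self.intervals.get(sub)
            if iv and pro and not (pro[0] <= iv[0] and iv[1] <= pro[1]):
                raise ConservationError(f"{sub} interval must lie inside pro")

    @classmethod
    def from_json(cls, path: str | Path) -> "DomainPartition":
        raw = json.loads(Path(path).read_text())
        reference = raw.pop("reference")
        intervals = {k: (int(v[0]), int(v[1])) for k, v in raw.items()}
        return cls(reference, intervals)

    def to_json(self, path: str | Path) -> None:
        out = {"reference": self.reference}
        out.update({k: list(v) for k, v in self.intervals.items()})
        Path(path).write_text(json.dumps(out, indent=2) + "\n")

    def domain_of(self, ref_coord: int) -> Optional[str]:
        """Innermost primary domain (pro/mature) containing the coordinate."""
        for name in ("pro", "mature"):
            iv = self.intervals.get(name)
            if iv and iv[0] <= ref_coord <= iv[1]:
                return name
        return None

    def columns_for(self, name: str, aln: Alignment) -> list[int]:
        """0-based alignment columns of interval ``name``, projected
        through the reference sequence's gap pattern."""
        if name not in self.intervals:
            raise ConservationError(f"unknown domain {name!r}")
        lo, hi = self.intervals[name]
        ref = aln.get(self.reference).residues
        ref_len = len(ref) - ref.count("-")
        if hi > ref_len:
            raise ConservationError(
                f"interval {name} [{lo},{hi}] exceeds ungapped reference "
                f"length {ref_len}"
            )
        cols, pos = [], 0
        for c, ch in enumerate(ref):
            if ch == "-":
                continue
            pos += 1
            if lo <= pos <= hi:
                cols.append(c)
        return cols


def default_reference(aln: Alignment) -> str:
    """Prefer a human sequence when identifiable, else the first record."""
    for r in aln.records:
        if "human" in r.id.lower() or r.id.lower().startswith("hsa"):
            logger.info("using %r as conservation reference", r.id)
            return r.id
    logger.info("no human sequence found; reference defaults to %r", aln.records[0].id)
    return aln.records[0].id


def _modal_residue(column: str) -> tuple[str, int]:
    """Modal non-gap residue and its count; alphabetical tie-break."""
    counts = Counter(ch for ch in column if ch not in _GAPLIKE)
    if not counts:
        return "-", 0
    best = max(counts.values())
    residue = min(ch for ch, c in counts.items() if c == best)
    return residue, best


@dataclass
class ConservationProfile:
    """Per-column modal residue and conservation percentage.

    ``ref_coords[i]`` is the 1-based ungapped reference coordinate of
    column ``i`` (``None`` where the reference is gapped).
    """

    modal: list[str]
    percent: list[float]
    ref_coords: list[Optional[int]]
    reference: str
    #: ungapped length of the reference in the profiled input; intervals
    #: beyond it are rejected even if their columns were filtered away
    ref_length: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "column": range(1, len(self.modal) + 1),
                "ref_coord": self.ref_coords,
                "modal_residue": self.modal,
                "conservation_pct": self.percent,
            }
        )


def conservation_profile(
    aln: Alignment, reference: Optional[str] = None
) -> ConservationProfile:
    """Modal-gap filter an alignment, then profile conservation.

    Unlike calling :func:`site_conservation` on a pre-filtered
    alignment, reference coordinates here are numbered on the *input*
    alignment's reference sequence, so domain partitions defined before
    filtering still map correctly even when the filter removes columns
    where the reference had a residue.
    """
    from .filtering import modal_gap_deletion

    if reference is None:
        reference = default_reference(aln)
    ref_seq = aln.get(reference).residues
    coord_of_column: list[Optional[int]] = []
    pos = 0
    for ch in ref_seq:
        if ch == "-":
            coord_of_column.append(None)
        else:
            pos += 1
            coord_of_column.append(pos)
    filtered = modal_gap_deletion(aln)
    profile = site_conservation(filtered.alignment, reference=reference)
    profile.ref_coords = [
        coord_of_column[c - 1] for c in filtered.retained_columns
    ]
    profile.ref_length = pos
    return profile


def site_conservation(
    aln: Alignment, reference: Optional[str] = None
) -> ConservationProfile:
    """Per-column conservation: 100 x (modal residue count) / n sequences.

    Expects modal-gap deletion to have been applied already; gap symbols
    still participate in the denominator but can no longer be modal.
    Ties between residues break alphabetically (the percentage is
    tie-order invariant).
    """
    if reference is None:
        reference = default_reference(aln)
    ref_seq = aln.get(reference).residues
    n = len(aln)
    modal, percent, ref_coords = [], [], []
    pos = 0
    for c in range(aln.length):
        residue, count = _modal_residue(aln.column(c))
        modal.append(residue)
        percent.append(100.0 * count / n)
        if ref_seq[c] == "-":
            ref_coords.append(None)
        else:
            pos += 1
            ref_coords.append(pos)
    return ConservationProfile(modal, percent, ref_coords, reference, pos)


def domain_summary(
    profile: ConservationProfile, partition: DomainPartition
) -> pd.DataFrame:
    """Mean conservation per domain interval, with column counts."""
    rows = []
    for name, (lo, hi) in partition.intervals.items():
        if hi > profile.ref_length:
            raise ConservationError(
                f"domain {name!r} [{lo},{hi}] exceeds the reference span "
                f"(1..{profile.ref_length})"
            )
        vals = [
            p
            for p, rc in zip(profile.percent, profile.ref_coords)
            if rc is not None and lo <= rc <= hi
        ]
        if not vals:
            raise ConservationError(f"domain {name!r} has no surviving columns")
        rows.append(
            {
                "domain": name,
                "mean_conservation_pct": sum(vals) / len(vals),
                "n_columns": len(vals),
            }
        )
    return pd.DataFrame(rows)


def modal_sequence(aln: Alignment, ids_subset: Sequence[str]) -> str:
    """Column-wise modal residues over a subset of sequences.

    Gaps are excluded from modality; an all-gap column emits ``-`` (and
    is logged).  Ties break alphabetically.
    """
    if not ids_subset:
        raise ConservationError("empty id subset")
    sub = aln.subset(ids_subset)
    out = []
    for c in range(sub.length):
        residue, count = _modal_residue(sub.column(c))
        if count == 0:
            logger.info("all-gap column %d in modal_sequence subset", c + 1)
        out.append(residue)
    return "".join(out)


def group_vs_modal(
    aln: Alignment,
    focal_ids: Sequence[str],
    reference_ids: Sequence[str],
    partition: DomainPartition,
) -> pd.DataFrame:
    """Percent identity of each focal sequence to the reference group's
    modal sequence, per domain.

    Columns where either symbol is a gap are excluded from both the
    numerator and the denominator.
    """
    if set(focal_ids) & set(reference_ids):
        raise ConservationError("focal and reference id sets must be disjoint")
    modal = modal_sequence(aln, reference_ids)
    rows = []
    for name in partition.intervals:
        cols = partition.columns_for(name, aln)
        for fid in focal_ids:
            seq = aln.get(fid).residues
            match = total = 0
            for c in cols:
                if seq[c] in _GAPLIKE or modal[c] in _GAPLIKE:
                    continue
                total += 1
                if seq[c] == modal[c]:
                    match += 1
            if total == 0:
                raise ConservationError(
                    f"domain {name!r} empty after gap exclusion for {fid!r}"
                )
            rows.append(
                {
                    "id": fid,
                    "domain": name,
                    "identity_pct": 100.0 * match / total,
                    "n_columns": total,
                }
            )
    return pd.DataFrame(rows)


def heatmap_table(
    profile: ConservationProfile,
    partition: DomainPartition,
    bins: tuple[float, float] = HEATMAP_BINS,
) -> pd.DataFrame:
    """Per-column conservation with domain labels and colour-scale bounds.

    The numeric values are exact; ``bins`` only annotates the intended
    colour range of a rendered heat map.
    """
    df = profile.to_frame()
    df["domain"] = [
        partition.domain_of(rc) if rc is not None else None
        for rc in profile.ref_coords
    ]
    df["scale_min"] = bins[0]
    df["scale_max"] = bins[1]
    return df
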