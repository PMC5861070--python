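"""Gap-elimination rules applied before the downstream analyses.

Two distinct rules are used, wired to different stages:

* **complete deletion** — drop every column containing *any* gap or
  missing character; applied before distance/tree estimation.
* **modal-gap deletion** — drop only columns whose modal character is a
  gap; applied before conservation profiling, which wants the maximal
  set of usable sites.

Gap ``-`` and missing data ``X`` (protein) / ``N`` (nucleotide) are
distinct symbols but both count as "gap or missing" here.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .seqio import Alignment

_MISSING = {"protein": {"X", "?"}, "nucleotide": {"N", "?"}}


class EmptyAfterFilterError(ValueError):
    """No columns survive the filter."""


@dataclass
class FilterResult:
    """Filtered alignment plus 1-based retained-column provenance."""

    alignment: Alignment
    retained_columns: tuple[int, ...]  # 1-based indices into the input

    def retained_tsv(self) -> str:
        lines = ["input_column\toutput_column"]
        for out_col, in_col in enumerate(self.retained_columns, start=1):
            lines.append(f"{in_col}\t{out_col}")
        return "\n".join(lines) + "\n"


def _gaplike(alphabet: str) -> set[str]:
    if alphabet not in _MISSING:
        raise ValueError(f"alphabet must be 'protein' or 'nucleotide', got {alphabet!r}")
    return {"-"} | _MISSING[alphabet]

def complete_deletion(aln: Alignment, alphabet: str = "protein") -> FilterResult:
    """Keep exactly the columns where no record has a gap or missing symbol."""
    bad = _gaplike(alphabet)
    keep = [
        c for c in range(aln.length)
        if not any(ch in bad for ch in aln.column(c))
    ]
    if not keep:
        raise EmptyAfterFilterError(
            "complete deletion removed every column of the alignment"
        )
    return FilterResult(aln.take_columns(keep), tuple(c + 1 for c in keep))


def modal_gap_deletion(aln: Alignment, alphabet: str = "protein") -> FilterResult:
    """Drop columns whose modal character is a gap.

    Gap and missing symbols pool into a single "gap" count.  A tie
    between the gap count and the best residue count *keeps* the column
    (maximal usable sites).
    """
    bad = _gaplike(alphabet)
    keep = []
    for c in range(aln.length):
        counts = Counter(aln.column(c))
        gap_count = sum(counts.pop(ch, 0) for ch in bad)
        best_residue = max(counts.values(), default=0)
        if gap_count <= best_residue:  # tie keeps the column
            keep.append(c)
    if not keep:
        raise EmptyAfterFilterError(
            "modal-gap deletion removed every column of the alignment"
        )
    return FilterResult(aln.take_columns(keep), tuple(c + 1 for c in keep))
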