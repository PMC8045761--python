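"""Initiation-context (Kozak) classification and uORF detection on 5'-UTRs.

The plant Kozak consensus used here is (A/G)nnATG(G): a purine three bases
upstream of the start codon (position -3) and a G immediately after it
(position +4). A "strong" context matches both sites, an "adequate" context
exactly one, a "weak" context neither; transcripts with an empty 5'-UTR form
their own "no 5'-UTR" category. A 1-2 nt UTR is not "no UTR": position -3 is
then missing (and never matches), so such transcripts classify through +4
alone.

uORFs are open reading frames starting at an ATG anywhere in the 5'-UTR. In
CONTAINED mode (default) only uORFs whose stop codon lies entirely within the
UTR are reported; ANY_START also reports upstream ATGs whose reading frame
runs into the CDS (stop in the CDS, or no stop at all). The minimum uORF is a
start codon immediately followed by a stop (one codon). Ambiguity bases (N)
never match ATG or a stop codon.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import TranscriptModel

__all__ = [
    "KozakCategory",
    "KozakCall",
    "UorfMode",
    "UorfRecord",
    "FrequencyTable",
    "kozak_context",
    "kozak_classify",
    "kozak_call",
    "find_uorfs",
    "feature_frequency",
    "feature_table",
    "MISSING",
]

MISSING = None  # sentinel for absent -3/+4 bases and undefined percentages

_PURINES = frozenset("AG")
_STOPS = frozenset(("TAA", "TAG", "TGA"))


class KozakCategory(str, Enum):
    STRONG = "STRONG"
    ADEQUATE = "ADEQUATE"
    WEAK = "WEAK"
    NO_UTR = "NO_UTR"


class UorfMode(str, Enum):
    CONTAINED = "CONTAINED"
    ANY_START = "ANY_START"


@dataclass(frozen=True)
class KozakCall:
    gene_id: str
    minus3: str | None
    plus4: str | None
    category: KozakCategory


@dataclass(frozen=True)
class UorfRecord:
    """One upstream ORF: 0-based offsets within the 5'-UTR.

    ``stop_offset`` is the first base of the in-frame stop codon measured from
    the start of the UTR (it may exceed the UTR length when the stop lies in
    the CDS), or None when the frame runs off the end of UTR+CDS without a
    stop. ``length_codons`` counts complete codons including the start and
    excluding the stop.
    """

    start_offset: int
    stop_offset: int | None
    contained: bool
    length_codons: int


def kozak_context(model: TranscriptModel) -> tuple[str | None, str | None]:
    """The (-3, +4) context bases of the main start codon; None where absent."""
    utr5, cds = model.utr5, model.cds
    minus3 = utr5[-3] if len(utr5) >= 3 else MISSING
    plus4 = cds[3] if len(cds) >= 4 else MISSING
    return minus3, plus4


def kozak_classify(
    minus3: str | None, plus4: str | None, has_utr: bool
) -> KozakCategory:
    """Category from the two context sites; a missing base never matches."""
    if not has_utr:
        return KozakCategory.NO_UTR
    m3 = minus3 is not MISSING and minus3 in _PURINES
    p4 = plus4 == "G"
    if m3 and p4:
        return KozakCategory.STRONG
    if m3 or p4:
        return KozakCategory.ADEQUATE
    return KozakCategory.WEAK


def kozak_call(model: TranscriptModel) -> KozakCall:
    minus3, plus4 = kozak_context(model)
    category = kozak_classify(minus3, plus4, has_utr=len(model.utr5) > 0)
    return KozakCall(model.gene_id, minus3, plus4, category)


def find_uorfs(
    utr5: str, cds: str = "", mode: UorfMode = UorfMode.CONTAINED
) -> list[UorfRecord]:
    """Scan every UTR position for an ATG and walk its reading frame.

    The frame is read in triplets across the concatenated UTR+CDS until a stop
    codon or the end of sequence. CONTAINED keeps only uORFs whose stop codon
    ends at or before the main start; ANY_START keeps every upstream ATG.
    Records are sorted by start offset.
    """
    mode = UorfMode(mode)
    utr5 = utr5.upper()
    full = utr5 + cds.upper()
    n_utr = len(utr5)
    records: list[UorfRecord] = []
    for start in range(n_utr - 2):
        if utr5[start : start + 3] != "ATG":
            continue
        stop_offset: int | None = None
        pos = start + 3
        while pos + 3 <= len(full):
            if full[pos : pos + 3] in _STOPS:
                stop_offset = pos
                break
            pos += 3
        if stop_offset is not None:
            length = (stop_offset - start) // 3
            contained = stop_offset + 3 <= n_utr
        else:
            length = (len(full) - start) // 3
            contained = False
        if mode is UorfMode.CONTAINED and not contained:
            continue
        records.append(UorfRecord(start, stop_offset, contained, length))
    return records


def _round1(value: float) -> float:
    """Half-up rounding to one decimal, as printed frequency tables use."""
    return float(Decimal(repr(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


_CATEGORY_COLUMNS = {
    KozakCategory.STRONG: "strong_pct",
    KozakCategory.ADEQUATE: "adequate_pct",
    KozakCategory.WEAK: "weak_pct",
    KozakCategory.NO_UTR: "no_utr_pct",
}


@dataclass
class FrequencyTable:
    """Per gene-set percentages of Kozak categories and uORF presence.

    ``rows`` maps a set label (plus "total_genes" for the background universe)
    to a dict with the four category percentages, ``uorf_pct``, the resolved
    denominator ``n``, and ``n_unresolved`` (set members without a
    representative transcript, excluded from percentages). Percentages are
    None for empty sets.
    """

    rows: dict[str, dict[str, float | int | None]]
    counts: dict[str, dict[str, int]]

    def to_frame(self) -> pd.DataFrame:
        order = ["strong_pct", "adequate_pct", "weak_pct", "no_utr_pct",
                 "uorf_pct", "n", "n_unresolved"]
        return pd.DataFrame.from_dict(self.rows, orient="index")[order]

    def to_tsv(self, path: str | Path) -> None:
        frame = self.to_frame()
        frame.index.name = "gene_set"
        frame.to_csv(path, sep="\t")

    def to_json(self, path: str | Path) -> None:
        payload = {"percentages": self.rows, "counts": self.counts}
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def feature_frequency(
    gene_sets: Mapping[str, Iterable[str]],
    calls: Mapping[str, KozakCall],
    uorf_counts: Mapping[str, int],
    universe: Iterable[str],
) -> FrequencyTable:
    """Frequency table of Kozak categories and uORF presence per gene set.

    Percentages use the resolved members (those with a Kozak call) as the
    denominator; members without a representative transcript are tallied in
    ``n_unresolved``. A "total_genes" row summarizes the whole universe.
    """
    rows: dict[str, dict[str, float | int | None]] = {}
    counts: dict[str, dict[str, int]] = {}
    labelled = {str(k): set(v) for k, v in gene_sets.items()}
    labelled["total_genes"] = set(universe)
    for label, members in labelled.items():
        resolved = [g for g in members if g in calls]
        n = len(resolved)
        tally = {cat: 0 for cat in KozakCategory}
        n_uorf = 0
        for g in resolved:
            tally[calls[g].category] += 1
            if uorf_counts.get(g, 0) >= 1:
                n_uorf += 1
        counts[label] = {
            **{_CATEGORY_COLUMNS[c]: tally[c] for c in KozakCategory},
            "uorf": n_uorf,
            "n": n,
            "n_unresolved": len(members) - n,
        }
        if n == 0:
            rows[label] = {
                **{_CATEGORY_COLUMNS[c]: None for c in KozakCategory},
                "uorf_pct": None, "n": 0, "n_unresolved": len(members),
            }
            continue
        rows[label] = {
            **{
                _CATEGORY_COLUMNS[c]: _round1(100.0 * tally[c] / n)
                for c in KozakCategory
            },
            "uorf_pct": _round1(100.0 * n_uorf / n),
            "n": n,
            "n_unresolved": len(members) - n,
        }
    return FrequencyTable(rows=rows, counts=counts)


def feature_table(
    models: Sequence[TranscriptModel], mode: UorfMode = UorfMode.CONTAINED
) -> pd.DataFrame:
    """Per-gene feature export: context bases, category, uORF counts (both modes)."""
    rows = []
    for m in models:
        call = kozak_call(m)
        rows.append(
            {
                "gene_id": m.gene_id,
                "minus3": call.minus3 or ".",
                "plus4": call.plus4 or ".",
                "kozak_category": call.category.value,
                "n_uorfs_contained": len(find_uorfs(m.utr5, m.cds, UorfMode.CONTAINED)),
                "n_uorfs_any": len(find_uorfs(m.utr5, m.cds, UorfMode.ANY_START)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "minus3", "plus4", "kozak_category",
                 "n_uorfs_contained", "n_uorfs_any"],
    )
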