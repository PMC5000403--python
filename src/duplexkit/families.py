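"""Grouping barcoded read pairs into strand-specific duplex families.

In a duplex sequencing library every original DNA fragment carries two random
12-bp tags, one at each end (called α and β).  A read pair observes them in
order αβ or βα depending on which strand of the fragment it derives from.
Concatenating the two tags in a fixed, order-normalised way yields a
*canonical barcode* that is identical for both strands of one fragment, so a
plain lexicographic sort of tagged reads groups the two strand families of
each fragment next to each other.

Grouping here is by exact barcode match only; tags containing ``N`` are kept
verbatim (such reads form their own families and are removed downstream by
family-size thresholds).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Tuple

from .seqio import FamilyTableRow, ReadPair

log = logging.getLogger(__name__)

DEFAULT_TAG_LEN = 12
DEFAULT_INVARIANT_LEN = 5  # constant linker between the tag and the insert


@dataclass(frozen=True)
class Barcode:
    """The α/β tag pair of one read pair and its order-normalised form."""

    alpha: str
    beta: str
    canonical: str
    tag_order: str  # "AB" if the physical read had α first, else "BA"


def canonical_barcode(alpha: str, beta: str, tag_len: int = DEFAULT_TAG_LEN) -> Barcode:
    """Normalise the (α, β) tag concatenation order by string comparison.

    ``canonical(α, β) == canonical(β, α)`` always; the physical order is
    recorded in ``tag_order``.  A tie (α == β) is defined as order AB.
    """
    if len(alpha) != tag_len or len(beta) != tag_len:
        raise ValueError(
            f"tags must be {tag_len}-mers, got lengths {len(alpha)} and {len(beta)}"
        )
    if alpha <= beta:
        return Barcode(alpha, beta, alpha + beta, "AB")
    return Barcode(alpha, beta, beta + alpha, "BA")


def extract_tags(
    pair: ReadPair,
    tag_len: int = DEFAULT_TAG_LEN,
    invariant_len: int = DEFAULT_INVARIANT_LEN,
) -> Tuple[Barcode, ReadPair]:
    """Split off the duplex tags and linker from both mates of a read pair.

    α is the first ``tag_len`` bases of mate 1 and β of mate 2; the tag plus
    the following ``invariant_len`` linker bases (and their qualities) are
    removed from each mate.  Reads too short to contain tag + linker + at
    least one payload base are rejected with :class:`ValueError`.
    """
    head = tag_len + invariant_len
    if len(pair.seq1) <= head or len(pair.seq2) <= head:
        raise ValueError(
            f"read {pair.name!r} shorter than tag+linker ({head} bp); rejected"
        )
    alpha = pair.seq1[:tag_len]
    beta = pair.seq2[:tag_len]
    bc = canonical_barcode(alpha, beta, tag_len)
    trimmed = ReadPair(
        pair.name,
        pair.seq1[head:],
        pair.qual1[head:],
        pair.seq2[head:],
        pair.qual2[head:],
    )
    return bc, trimmed


def pair_to_rows(bc: Barcode, pair: ReadPair) -> Tuple[FamilyTableRow, FamilyTableRow]:
    """One family-table row per mate of a tagged, trimmed read pair."""
    return (
        FamilyTableRow(bc.canonical, bc.tag_order, 1, pair.name, pair.seq1, pair.qual1),
        FamilyTableRow(bc.canonical, bc.tag_order, 2, pair.name, pair.seq2, pair.qual2),
    )


def make_family_table(
    pairs: Iterable[ReadPair],
    tag_len: int = DEFAULT_TAG_LEN,
    invariant_len: int = DEFAULT_INVARIANT_LEN,
) -> Tuple[list[FamilyTableRow], int]:
    """Tag, trim and sort a stream of read pairs into family-table rows.

    Returns ``(rows sorted by (barcode, tag_order, mate, name), n_rejected)``
    where rejected pairs are those with a mate too short to carry a tag.
    """
    rows: list[FamilyTableRow] = []
    n_rejected = 0
    for pair in pairs:
        try:
            bc, trimmed = extract_tags(pair, tag_len, invariant_len)
        except ValueError:
            n_rejected += 1
            continue
        rows.extend(pair_to_rows(bc, trimmed))
    if n_rejected:
        log.info("rejected %d read pairs shorter than tag+linker", n_rejected)
    rows.sort(key=FamilyTableRow.sort_key)
    return rows, n_rejected


@dataclass
class ReadFamily:
    """All read pairs sharing one canonical barcode, split by tag order.

    The ``ab`` and ``ba`` lists hold the (trimmed) read pairs whose physical
    tag order was αβ and βα respectively — the two single-stranded families
    of one original fragment.
    """

    canonical_barcode: str
    ab: list[ReadPair] = field(default_factory=list)
    ba: list[ReadPair] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.ab) + len(self.ba)

    @property
    def is_duplex(self) -> bool:
        return bool(self.ab) and bool(self.ba)


def _rows_to_pairs(barcode: str, rows: list[FamilyTableRow]) -> list[ReadPair]:
    by_name: dict[str, dict[int, FamilyTableRow]] = {}
    order: list[str] = []
    for row in rows:
        if row.read_name not in by_name:
            by_name[row.read_name] = {}
            order.append(row.read_name)
        by_name[row.read_name][row.mate] = row
    pairs = []
    for name in order:
        mates = by_name[name]
        if set(mates) != {1, 2}:
            raise ValueError(f"family {barcode}: read {name!r} is missing a mate row")
        pairs.append(
            ReadPair(name, mates[1].seq, mates[1].qual, mates[2].seq, mates[2].qual)
        )
    return pairs


def group_families(rows: Iterable[FamilyTableRow]) -> Iterator[ReadFamily]:
    """Group (sorted or unsorted) family-table rows into one family per barcode.

    Families are emitted in sorted canonical-barcode order with members
    partitioned by tag order; the total number of read pairs out equals the
    number in.
    """
    rows = sorted(rows, key=FamilyTableRow.sort_key)
    i = 0
    while i < len(rows):
        bc = rows[i].canonical_barcode
        j = i
        ab_rows: list[FamilyTableRow] = []
        ba_rows: list[FamilyTableRow] = []
        while j < len(rows) and rows[j].canonical_barcode == bc:
            (ab_rows if rows[j].tag_order == "AB" else ba_rows).append(rows[j])
            j += 1
        yield ReadFamily(bc, _rows_to_pairs(bc, ab_rows), _rows_to_pairs(bc, ba_rows))
        i = j


# Row labels mirror the standard accounting of a duplex experiment.
CENSUS_ROWS = (
    "read_pairs",
    "unique_tags",
    "unique_tags_with_1_pair",
    "unique_ab",
    "unique_ab_with_1_pair",
    "unique_ab_with_ge_k_pairs",
    "unique_ba",
    "unique_ba_with_1_pair",
    "unique_ba_with_ge_k_pairs",
    "unique_duplex",
    "unique_duplex_ge_k_both_strands",
    "reads_in_duplex_ge_k_both_strands",
)


def family_census(families: Iterable[ReadFamily], k: int = 3) -> dict[str, int]:
    """Tally a grouped family stream the way duplex experiments are reported.

    ``unique_tags`` counts distinct canonical barcodes; αβ/βα configurations
    are strand families with at least one read pair in that tag order;
    ``unique_duplex`` are barcodes with both orders present; the ``ge_k``
    rows apply the family-size threshold ``k`` (default 3) per strand.
    """
    c = {name: 0 for name in CENSUS_ROWS}
    for fam in families:
        c["read_pairs"] += fam.n_pairs
        c["unique_tags"] += 1
        c["unique_tags_with_1_pair"] += fam.n_pairs == 1
        if fam.ab:
            c["unique_ab"] += 1
            c["unique_ab_with_1_pair"] += len(fam.ab) == 1
            c["unique_ab_with_ge_k_pairs"] += len(fam.ab) >= k
        if fam.ba:
            c["unique_ba"] += 1
            c["unique_ba_with_1_pair"] += len(fam.ba) == 1
            c["unique_ba_with_ge_k_pairs"] += len(fam.ba) >= k
        if fam.is_duplex:
            c["unique_duplex"] += 1
            if len(fam.ab) >= k and len(fam.ba) >= k:
                c["unique_duplex_ge_k_both_strands"] += 1
                c["reads_in_duplex_ge_k_both_strands"] += fam.n_pairs
    return c


def singleton_fraction(families: Iterable[ReadFamily]) -> tuple[int, int, float]:
    """(n_unique_barcodes, n_singletons, fraction seen exactly once)."""
    n_unique = 0
    n_single = 0
    for fam in families:
        n_unique += 1
        n_single += fam.n_pairs == 1
    return n_unique, n_single, (n_single / n_unique if n_unique else 0.0)
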