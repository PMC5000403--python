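"""Single-stranded and duplex consensus calling.

A single-stranded consensus sequence (SSCS) is called column-by-column from
the multiple alignment of one strand family: the strict majority character
among quality-passing votes wins, otherwise ``N``.  Gaps vote like bases; a
gap's quality is a weighted average of the eight nearest real base qualities
of its row (four per side, weight falling linearly with rank distance).

A duplex consensus sequence (DCS) reconciles the two SSCSs of a fragment: the
sequences are locally aligned (Smith–Waterman) and compared base by base —
agreement keeps the base, a substitution disagreement becomes the two-base
IUPAC ambiguity code, and a gap opposite a base (or any ``N``) becomes ``N``.

The per-column scalar routines (:func:`call_column`, :func:`gap_quality`) are
the reference semantics; :func:`call_sscs` applies the same rules through a
vectorised path so that large runs stay fast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .msa import GAP_CHAR, GAP_QUAL_PLACEHOLDER, AlignedFamily, LocalAlignment, smith_waterman
from .seqio import PHRED_OFFSET

log = logging.getLogger(__name__)

DEFAULT_MIN_READS = 3
DEFAULT_QUAL_THRESH = 20

# Neighbourhood weights for gap quality: rank distance d = 1..4 on each side
# gets weight 5 - d (4, 3, 2, 1), renormalised when fewer neighbours exist.
_GAP_NEIGHBORS_PER_SIDE = 4


@dataclass
class SSCS:
    """Consensus of one single-stranded family (one tag order, one mate)."""

    canonical_barcode: str
    tag_order: str
    mate: int
    seq: str
    n_reads: int


@dataclass
class DCS:
    """Duplex consensus built from the two opposite-strand SSCSs of a fragment."""

    canonical_barcode: str
    mate: int
    seq: str
    n_reads_ab: int
    n_reads_ba: int


def gap_quality(gapped_qual_row: Sequence, position: int) -> float:
    """Quality assigned to a gap: weighted mean of the nearest base qualities.

    Up to four non-gap neighbours are taken on each side of ``position`` in
    this row; the neighbour at rank distance d (1 = nearest) gets weight
    ``5 - d``.  Near the ends fewer neighbours contribute and the weights are
    renormalised.  A row with no real base at all scores 0.

    ``gapped_qual_row`` may be a quality string (Sanger-encoded, with
    :data:`~duplexkit.msa.GAP_QUAL_PLACEHOLDER` at gaps) or a sequence of
    ints/None.
    """

    def score(x) -> Optional[float]:
        if x is None or x == GAP_QUAL_PLACEHOLDER:
            return None
        if isinstance(x, str):
            return float(ord(x) - PHRED_OFFSET)
        return float(x)

    total = 0.0
    wsum = 0.0
    for step in (-1, 1):
        found = 0
        i = position + step
        while 0 <= i < len(gapped_qual_row) and found < _GAP_NEIGHBORS_PER_SIDE:
            q = score(gapped_qual_row[i])
            if q is not None:
                found += 1
                w = _GAP_NEIGHBORS_PER_SIDE + 1 - found
                total += w * q
                wsum += w
            i += step
    if wsum == 0.0:
        return 0.0
    return total / wsum


def call_column(
    bases: Sequence[str],
    quals: Sequence[float],
    qual_thresh: float = DEFAULT_QUAL_THRESH,
) -> str:
    """Majority call for one alignment column.

    Characters (gaps included) whose quality passes ``qual_thresh`` vote; the
    character with strictly more than half of the counted votes wins,
    otherwise ``N``.  If nothing passes the filter the call is ``N``.
    """
    if len(bases) == 0:
        raise ValueError("empty alignment column")
    if len(bases) != len(quals):
        raise ValueError("bases and quals differ in length")
    counts: dict[str, int] = {}
    total = 0
    for b, q in zip(bases, quals):
        if q >= qual_thresh:
            counts[b] = counts.get(b, 0) + 1
            total += 1
    if total == 0:
        return "N"
    best_char, best_n = max(counts.items(), key=lambda kv: kv[1])
    if 2 * best_n > total:
        return best_char
    return "N"


_CONS_ALPHABET = np.frombuffer(b"ACGTN-", dtype=np.uint8)


def _quality_matrix(fam: AlignedFamily) -> np.ndarray:
    """Per-cell qualities with computed gap qualities substituted at gaps."""
    n = len(fam.rows)
    width = len(fam.rows[0])
    q = np.empty((n, width), dtype=np.float64)
    for i, (row, qrow) in enumerate(zip(fam.rows, fam.gapped_quals)):
        base = np.frombuffer(qrow.encode("latin-1"), dtype=np.uint8).astype(np.float64)
        base -= PHRED_OFFSET
        q[i] = base
        if GAP_CHAR in row:
            for j, ch in enumerate(row):
                if ch == GAP_CHAR:
                    q[i, j] = gap_quality(qrow, j)
    return q


def consensus_from_alignment(
    fam: AlignedFamily, qual_thresh: float = DEFAULT_QUAL_THRESH
) -> str:
    """Column-wise consensus of an aligned family, gap columns removed."""
    mat = np.vstack(
        [np.frombuffer(row.encode("ascii"), dtype=np.uint8) for row in fam.rows]
    )
    quals = _quality_matrix(fam)
    counted = quals >= qual_thresh
    votes = np.stack(
        [((mat == code) & counted).sum(axis=0) for code in _CONS_ALPHABET]
    )  # 6 x width
    total = votes.sum(axis=0)
    winner = votes.argmax(axis=0)
    best = votes.max(axis=0)
    chars = _CONS_ALPHABET[winner]
    is_n = (total == 0) | (2 * best <= total)
    chars = np.where(is_n, ord("N"), chars)
    out = chars.astype(np.uint8).tobytes().decode("ascii")
    return out.replace(GAP_CHAR, "")


def call_sscs(
    fam: AlignedFamily,
    min_reads: int = DEFAULT_MIN_READS,
    qual_thresh: float = DEFAULT_QUAL_THRESH,
    canonical_barcode: str = "",
    tag_order: str = "AB",
    mate: int = 1,
) -> Optional[SSCS]:
    """Call the SSCS of one aligned strand family, or ``None`` below threshold.

    Families with fewer than ``min_reads`` members produce no consensus.
    Columns whose consensus character is a gap are dropped from the output.
    """
    n = len(fam.rows)
    if n < min_reads:
        return None
    seq = consensus_from_alignment(fam, qual_thresh)
    return SSCS(canonical_barcode, tag_order, mate, seq, n)


_IUPAC2 = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GC"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}
_VALID_PAIR_CHARS = set("ACGTN-")


def iupac_pair(b1: str, b2: str) -> str:
    """Reconcile one aligned base pair from the two strands of a duplex.

    Agreement keeps the base; two different real bases give their two-base
    IUPAC ambiguity code; any pairing involving a gap or an ``N`` gives ``N``
    (single-strand evidence is never allowed to outvote ignorance).
    """
    if b1 not in _VALID_PAIR_CHARS or b2 not in _VALID_PAIR_CHARS:
        raise ValueError(f"invalid characters for duplex reconciliation: {b1!r}, {b2!r}")
    if GAP_CHAR in (b1, b2) or "N" in (b1, b2):
        return "N"
    if b1 == b2:
        return b1
    return _IUPAC2[frozenset((b1, b2))]


def call_dcs(
    sscs_ab: SSCS,
    sscs_ba: SSCS,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -1.0,
) -> Optional[DCS]:
    """Duplex consensus from the two opposite-strand SSCSs of one fragment.

    The SSCSs are Smith–Waterman aligned and each aligned column reconciled
    with :func:`iupac_pair`; columns outside the local alignment are excluded.
    Returns ``None`` if either SSCS is empty or nothing aligns.
    """
    if sscs_ab.canonical_barcode != sscs_ba.canonical_barcode:
        raise ValueError("SSCSs from different canonical barcodes")
    if not sscs_ab.seq or not sscs_ba.seq:
        return None
    if sscs_ab.seq == sscs_ba.seq:
        aligned_a, aligned_b = sscs_ab.seq, sscs_ba.seq
    else:
        aln: LocalAlignment = smith_waterman(
            sscs_ab.seq, sscs_ba.seq, match, mismatch, gap_open, gap_extend
        )
        if not aln.aligned_a:
            log.warning(
                "no local alignment between the SSCSs of %s; DCS dropped",
                sscs_ab.canonical_barcode,
            )
            return None
        if aln.a_end - aln.a_start < len(sscs_ab.seq) or aln.b_end - aln.b_start < len(
            sscs_ba.seq
        ):
            log.debug(
                "duplex alignment of %s truncates the SSCSs (%d/%d and %d/%d bases kept)",
                sscs_ab.canonical_barcode,
                aln.a_end - aln.a_start,
                len(sscs_ab.seq),
                aln.b_end - aln.b_start,
                len(sscs_ba.seq),
            )
        aligned_a, aligned_b = aln.aligned_a, aln.aligned_b
    seq = "".join(iupac_pair(x, y) for x, y in zip(aligned_a, aligned_b))
    return DCS(sscs_ab.canonical_barcode, sscs_ab.mate, seq, sscs_ab.n_reads, sscs_ba.n_reads)


UNPAIRED_POLICIES = ("include", "separate", "discard")


def route_unpaired_sscs(sscs: SSCS, policy: str) -> Optional[str]:
    """Disposition of an SSCS with no opposite-strand partner.

    Returns the destination stream: ``"main"`` (emitted with the DCS output,
    flagged single-stranded), ``"sscs"`` (a separate SSCS-only file) or
    ``None`` (discarded).
    """
    if policy == "include":
        return "main"
    if policy == "separate":
        return "sscs"
    if policy == "discard":
        return None
    raise ValueError(f"unknown unpaired-SSCS policy {policy!r}")


def trim_ambiguous(
    seq: str,
    mode: str = "trim",
    max_frac_n: float = 0.3,
    window: int = 10,
) -> Optional[str]:
    """Remove or trim consensus sequences dominated by ambiguous characters.

    ``mode="remove"`` drops the whole sequence when the fraction of non-ACGT
    characters exceeds ``max_frac_n``.  ``mode="trim"`` walks a sliding
    window in from each end and cuts until the window's ambiguous fraction is
    within ``max_frac_n`` and the boundary base itself is unambiguous; if an
    interior window still exceeds the threshold, only the prefix up to it is
    kept.  Returns the (possibly empty) sequence, or ``None`` when removed.
    """
    if mode not in ("trim", "remove"):
        raise ValueError(f"unknown trim mode {mode!r}")
    if not seq:
        return None if mode == "remove" else ""
    ambig = [c not in "ACGT" for c in seq]
    if mode == "remove":
        return None if sum(ambig) / len(seq) > max_frac_n else seq

    n = len(seq)
    w = min(window, n)

    def frac(i: int) -> float:
        j = min(i + w, n)
        start = max(0, j - w)
        return sum(ambig[start:j]) / (j - start)

    left = 0
    while left < n and (ambig[left] or frac(left) > max_frac_n):
        left += 1
    right = n
    while right > left and (ambig[right - 1] or frac(max(left, right - w)) > max_frac_n):
        right -= 1
    # keep only the prefix up to the first interior window over threshold
    for i in range(left, right - w + 1):
        if sum(ambig[i : i + w]) / w > max_frac_n:
            right = min(right, i + w - 1)
            while right > left and ambig[right - 1]:
                right -= 1
            break
    return seq[left:right]
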