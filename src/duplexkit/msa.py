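"""Alignment primitives for duplex consensus calling.

Two alignment problems arise in the pipeline and both involve near-identical
sequences: the reads within one single-stranded family must be stacked into a
multiple alignment before per-column consensus calling, and the two
single-stranded consensi of a fragment must be reconciled with a local
(Smith–Waterman) alignment before duplex consensus calling.

The built-in family aligner is a deterministic center-star progressive
alignment: the longest read is the center, every other read is globally
aligned to it (edlib's C Needleman–Wunsch) and the pairwise alignments are
merged on the center's coordinate system.  For reads that differ only by a
handful of errors this is for all practical purposes optimal, and it is
exactly reproducible.  An optional backend shells out to MAFFT when a
general-purpose MSA is preferred.

The Smith–Waterman implementation uses affine gap scoring (Gotoh) with a
numba-compiled fill and a deterministic traceback preferring
diagonal > up > left.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from typing import Sequence

import edlib
import numpy as np
from numba import njit

log = logging.getLogger(__name__)

GAP_CHAR = "-"
GAP_QUAL_PLACEHOLDER = " "  # sentinel in gapped quality strings; never a real Phred


@dataclass
class AlignedFamily:
    """A gapped stack of the reads of one family (one strand, one mate)."""

    rows: list[str]
    gapped_quals: list[str]
    names: list[str]

    def __post_init__(self) -> None:
        if self.rows:
            width = len(self.rows[0])
            if any(len(r) != width for r in self.rows):
                raise ValueError("alignment rows differ in length")
            if any(len(q) != width for q in self.gapped_quals):
                raise ValueError("gapped quality rows differ in length from rows")


@dataclass
class LocalAlignment:
    """A local alignment of two sequences under affine gap scoring."""

    aligned_a: str
    aligned_b: str
    score: float
    a_start: int
    a_end: int
    b_start: int
    b_end: int


_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE.get(c, 4) for c in seq], dtype=np.uint8)


@njit(cache=True)
def _gotoh_fill(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n = a.shape[0]
    m = b.shape[0]
    NEG = -1e30
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            e = H[i, j - 1] + gap_open
            e2 = E[i, j - 1] + gap_extend
            if e2 > e:
                e = e2
            E[i, j] = e
            f = H[i - 1, j] + gap_open
            f2 = F[i - 1, j] + gap_extend
            if f2 > f:
                f = f2
            F[i, j] = f
            # N never matches anything, including N
            if ai == b[j - 1] and ai != 4:
                s = match
            else:
                s = mismatch
            h = H[i - 1, j - 1] + s
            if f > h:
                h = f
            if e > h:
                h = e
            if h < 0.0:
                h = 0.0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return H, E, F, best, bi, bj


def smith_waterman(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -1.0,
) -> LocalAlignment:
    """Optimal local alignment of two sequences (Gotoh affine gaps).

    A gap of length g scores ``gap_open + (g-1)*gap_extend``.  ``N`` is scored
    as a mismatch against everything (including ``N``).  Ties during traceback
    are broken deterministically, preferring diagonal, then up (gap in ``b``),
    then left; the reported optimum is the first-encountered maximal cell in
    row-major order.  An all-mismatch input yields an empty, zero-score
    alignment.
    """
    if not a or not b:
        raise ValueError("smith_waterman requires non-empty sequences")
    H, E, F, best, bi, bj = _gotoh_fill(
        _encode(a), _encode(b), float(match), float(mismatch), float(gap_open), float(gap_extend)
    )
    if best <= 0.0:
        return LocalAlignment("", "", 0.0, 0, 0, 0, 0)
    eps = 1e-9
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = bi, bj
    state = "H"
    while True:
        if state == "H":
            if H[i, j] <= eps:
                break
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else mismatch
            if abs(H[i, j] - (H[i - 1, j - 1] + s)) < eps:
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                i -= 1
                j -= 1
            elif abs(H[i, j] - F[i, j]) < eps:
                state = "F"
            else:
                state = "E"
        elif state == "F":  # gap in b, consume a
            out_a.append(a[i - 1])
            out_b.append(GAP_CHAR)
            closed = abs(F[i, j] - (H[i - 1, j] + gap_open)) < eps
            i -= 1
            if closed:
                state = "H"
        else:  # state == "E": gap in a, consume b
            out_a.append(GAP_CHAR)
            out_b.append(b[j - 1])
            closed = abs(E[i, j] - (H[i, j - 1] + gap_open)) < eps
            j -= 1
            if closed:
                state = "H"
    return LocalAlignment(
        "".join(reversed(out_a)),
        "".join(reversed(out_b)),
        float(best),
        i,
        bi,
        j,
        bj,
    )


def _pairwise_to_center(read: str, center: str) -> tuple[str, str]:
    """Global (NW) alignment of read vs center as two gapped strings."""
    if read == center:
        return read, center
    res = edlib.align(read, center, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, read, center)
    return nice["query_aligned"], nice["target_aligned"]


def _merge_center_star(
    seqs: Sequence[str], quals: Sequence[str], center_idx: int
) -> tuple[list[str], list[str]]:
    center = seqs[center_idx]
    lc = len(center)
    # per read: inserted (char, qualchar) runs keyed by the center position they
    # precede, plus the read character aligned to each center base
    read_at = []
    read_ins = []
    master_ins = [0] * (lc + 1)
    for k, seq in enumerate(seqs):
        if k == center_idx:
            read_at.append(None)
            read_ins.append(None)
            continue
        q_al, c_al = _pairwise_to_center(seq, center)
        at: list[tuple[str, str]] = []
        ins: dict[int, list[tuple[str, str]]] = {}
        qi = 0  # index into the read's own quality string
        c = 0  # next center base index
        for rc, cc in zip(q_al, c_al):
            if cc == GAP_CHAR:
                ins.setdefault(c, []).append((rc, quals[k][qi]))
                qi += 1
            else:
                if rc == GAP_CHAR:
                    at.append((GAP_CHAR, GAP_QUAL_PLACEHOLDER))
                else:
                    at.append((rc, quals[k][qi]))
                    qi += 1
                c += 1
        read_at.append(at)
        read_ins.append(ins)
        for pos, run in ins.items():
            if len(run) > master_ins[pos]:
                master_ins[pos] = len(run)

    rows = []
    qrows = []
    for k in range(len(seqs)):
        chars: list[str] = []
        qchars: list[str] = []
        if k == center_idx:
            for c in range(lc):
                chars.append(GAP_CHAR * master_ins[c] + center[c])
                qchars.append(GAP_QUAL_PLACEHOLDER * master_ins[c] + quals[k][c])
            chars.append(GAP_CHAR * master_ins[lc])
            qchars.append(GAP_QUAL_PLACEHOLDER * master_ins[lc])
        else:
            at = read_at[k]
            ins = read_ins[k]
            for c in range(lc):
                run = ins.get(c, [])
                pad = master_ins[c] - len(run)
                chars.append("".join(x[0] for x in run) + GAP_CHAR * pad + at[c][0])
                qchars.append(
                    "".join(x[1] for x in run) + GAP_QUAL_PLACEHOLDER * pad + at[c][1]
                )
            run = ins.get(lc, [])
            pad = master_ins[lc] - len(run)
            chars.append("".join(x[0] for x in run) + GAP_CHAR * pad)
            qchars.append("".join(x[1] for x in run) + GAP_QUAL_PLACEHOLDER * pad)
        rows.append("".join(chars))
        qrows.append("".join(qchars))
    return rows, qrows


def align_family(
    seqs: Sequence[str],
    quals: Sequence[str],
    names: Sequence[str] | None = None,
    backend: str = "builtin",
) -> AlignedFamily:
    """Multiple alignment of the reads of one family (one strand, one mate).

    Removing gaps from row *i* recovers input read *i* exactly; gap positions
    carry :data:`GAP_QUAL_PLACEHOLDER` in the gapped quality rows (consensus
    calling substitutes a neighbourhood-weighted quality there).
    """
    if not seqs:
        raise ValueError("align_family requires at least one read")
    if len(seqs) != len(quals):
        raise ValueError("seqs and quals differ in length")
    names = list(names) if names is not None else [f"read{i}" for i in range(len(seqs))]
    if len(seqs) == 1:
        return AlignedFamily([seqs[0]], [quals[0]], names)
    if backend == "mafft":
        return _align_family_mafft(seqs, quals, names)
    if backend != "builtin":
        raise ValueError(f"unknown MSA backend {backend!r}")
    if len(set(seqs)) == 1:
        return AlignedFamily(list(seqs), list(quals), names)
    center_idx = max(range(len(seqs)), key=lambda i: (len(seqs[i]), -i))
    rows, qrows = _merge_center_star(seqs, quals, center_idx)
    return AlignedFamily(rows, qrows, names)


def _align_family_mafft(
    seqs: Sequence[str], quals: Sequence[str], names: list[str]
) -> AlignedFamily:
    """Shell out to an installed MAFFT binary and re-attach qualities."""
    if shutil.which("mafft") is None:
        raise RuntimeError("MAFFT backend requested but no 'mafft' executable found")
    with tempfile.NamedTemporaryFile("wt", suffix=".fa") as tmp:
        for i, seq in enumerate(seqs):
            tmp.write(f">{i}\n{seq}\n")
        tmp.flush()
        out = subprocess.run(
            ["mafft", "--quiet", "--nuc", "--retree", "2", tmp.name],
            capture_output=True,
            text=True,
            check=True,
        ).stdout
    aligned: dict[int, str] = {}
    key = None
    for line in out.splitlines():
        if line.startswith(">"):
            key = int(line[1:].strip())
            aligned[key] = ""
        elif key is not None:
            aligned[key] += line.strip().upper()
    rows = [aligned[i] for i in range(len(seqs))]
    qrows = []
    for row, qual in zip(rows, quals):
        qi = 0
        qchars = []
        for ch in row:
            if ch == GAP_CHAR:
                qchars.append(GAP_QUAL_PLACEHOLDER)
            else:
                qchars.append(qual[qi])
                qi += 1
        if qi != len(qual):
            raise RuntimeError("MAFFT output does not degap to the input read")
        qrows.append("".join(qchars))
    return AlignedFamily(rows, qrows, names)
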