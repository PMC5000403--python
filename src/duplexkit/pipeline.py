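"""The end-to-end consensus pipeline: families -> alignment -> SSCS -> DCS.

One call (:func:`run_pipeline`) chains the stages in memory exactly as the
per-stage command-line tools chain them through files: tag extraction and
family grouping, per-family multiple alignment, single-stranded consensus
calling with a family-size threshold, duplex reconciliation, optional
ambiguity trimming, and FASTA output with a read-accounting report.

Mate geometry: the mate-1 reads of the αβ family cover the same physical
end of the fragment as the mate-2 reads of the βα family (opposite tag
order means opposite strand, so the mates swap).  DCS mate 1 therefore
reconciles SSCS(AB, mate 1) with SSCS(BA, mate 2), and DCS mate 2 the other
two.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from . import families as fam_mod
from . import seqio
from .consensus import (
    DCS,
    SSCS,
    call_dcs,
    call_sscs,
    route_unpaired_sscs,
    trim_ambiguous,
)
from .msa import align_family

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable parameters of the consensus pipeline."""

    tag_len: int = 12
    invariant_len: int = 5
    min_reads: int = 3
    qual_thresh: float = 20.0
    sscs_policy: str = "separate"  # include | separate | discard
    trim_mode: Optional[str] = None  # None | trim | remove
    max_frac_n: float = 0.3
    trim_window: int = 10
    fixed_phred: int = 40
    msa_backend: str = "builtin"
    sw_match: float = 1.0
    sw_mismatch: float = -1.0
    sw_gap_open: float = -2.0
    sw_gap_extend: float = -1.0


@dataclass
class ConsensusOutput:
    """Consensus sequences and accounting for one pipeline run."""

    dcs: list[DCS] = field(default_factory=list)
    sscs_main: list[SSCS] = field(default_factory=list)  # unpaired, policy=include
    sscs_separate: list[SSCS] = field(default_factory=list)
    report: dict = field(default_factory=dict)


def _strand_groups(family: fam_mod.ReadFamily):
    """The four (tag_order, mate) read groups of one family.

    Yields ``(tag_order, mate, seqs, quals)``; mate here is the mate label
    of the physical reads, so the duplex partner of (AB, 1) is (BA, 2).
    """
    for order, pairs in (("AB", family.ab), ("BA", family.ba)):
        if not pairs:
            continue
        yield order, 1, [p.seq1 for p in pairs], [p.qual1 for p in pairs]
        yield order, 2, [p.seq2 for p in pairs], [p.qual2 for p in pairs]


def consensus_for_family(
    family: fam_mod.ReadFamily, cfg: PipelineConfig
) -> tuple[list[DCS], list[SSCS]]:
    """SSCS and DCS calls for one grouped family.

    Returns ``(dcs_list, unpaired_sscs_list)`` — up to two DCSs (one per
    mate) and the SSCSs that had no qualifying opposite-strand partner.
    """
    sscs: dict[tuple[str, int], SSCS] = {}
    for order, mate, seqs, quals in _strand_groups(family):
        if len(seqs) < cfg.min_reads:
            continue
        aligned = align_family(seqs, quals, backend=cfg.msa_backend)
        result = call_sscs(
            aligned,
            min_reads=cfg.min_reads,
            qual_thresh=cfg.qual_thresh,
            canonical_barcode=family.canonical_barcode,
            tag_order=order,
            mate=mate,
        )
        if result is not None and result.seq:
            sscs[(order, mate)] = result

    dcs_out: list[DCS] = []
    unpaired: list[SSCS] = []
    # DCS mate m pairs (AB, m) with (BA, opposite mate)
    for dcs_mate in (1, 2):
        ab = sscs.get(("AB", dcs_mate))
        ba = sscs.get(("BA", 3 - dcs_mate))
        if ab is not None and ba is not None:
            dcs = call_dcs(
                ab, ba, cfg.sw_match, cfg.sw_mismatch, cfg.sw_gap_open, cfg.sw_gap_extend
            )
            if dcs is not None:
                dcs = DCS(dcs.canonical_barcode, dcs_mate, dcs.seq, dcs.n_reads_ab, dcs.n_reads_ba)
                dcs_out.append(dcs)
                continue
        for s in (ab, ba):
            if s is not None:
                unpaired.append(s)
    return dcs_out, unpaired


def call_consensi(
    grouped: Iterable[fam_mod.ReadFamily], cfg: PipelineConfig
) -> ConsensusOutput:
    """Run consensus calling over a grouped family stream."""
    out = ConsensusOutput()
    n_families = 0
    n_pairs = 0
    n_pairs_used = 0
    n_sscs = 0
    for family in grouped:
        n_families += 1
        n_pairs += family.n_pairs
        dcs_list, unpaired = consensus_for_family(family, cfg)
        n_sscs += 2 * len(dcs_list) + len(unpaired)
        out.dcs.extend(dcs_list)
        if dcs_list:
            n_pairs_used += family.n_pairs
        for s in unpaired:
            dest = route_unpaired_sscs(s, cfg.sscs_policy)
            if dest == "main":
                out.sscs_main.append(s)
            elif dest == "sscs":
                out.sscs_separate.append(s)
    if cfg.trim_mode is not None:
        out.dcs = [
            DCS(d.canonical_barcode, d.mate, trimmed, d.n_reads_ab, d.n_reads_ba)
            for d in out.dcs
            if (trimmed := trim_ambiguous(d.seq, cfg.trim_mode, cfg.max_frac_n, cfg.trim_window))
        ]
    out.report = {
        "families": n_families,
        "read_pairs_in_families": n_pairs,
        "sscs_called": n_sscs,
        "dcs_called": len(out.dcs),
        "read_pairs_in_dcs_families": n_pairs_used,
        "read_pairs_discarded": n_pairs - n_pairs_used,
    }
    return out


def _dcs_records(dcs_list: list[DCS], mate: int) -> Iterator[tuple[str, str]]:
    for d in dcs_list:
        if d.mate == mate:
            yield f"{d.canonical_barcode}.{d.n_reads_ab}.{d.n_reads_ba}", d.seq


def _sscs_records(sscs_list: list[SSCS], mate: int) -> Iterator[tuple[str, str]]:
    for s in sscs_list:
        if s.mate == mate:
            yield f"{s.canonical_barcode}.{s.tag_order}.{s.n_reads}.sscs", s.seq


def run_pipeline(
    fastq1,
    fastq2,
    out_prefix: str,
    cfg: PipelineConfig | None = None,
) -> dict:
    """Run the whole pipeline on a FASTQ pair; write FASTA outputs + report.

    Writes ``{out_prefix}_dcs_1.fa`` / ``_dcs_2.fa`` (with unpaired SSCSs
    appended when the policy is ``include``) and, when the policy is
    ``separate``, ``{out_prefix}_sscs_1.fa`` / ``_sscs_2.fa``.  Returns the
    run report, which satisfies the accounting identity
    ``read_pairs_in == pairs in DCS families + pairs discarded + pairs
    rejected at tagging``.
    """
    cfg = cfg or PipelineConfig()
    pairs = seqio.read_paired_fastq(fastq1, fastq2)
    rows, n_rejected = fam_mod.make_family_table(pairs, cfg.tag_len, cfg.invariant_len)
    grouped = fam_mod.group_families(rows)
    out = call_consensi(grouped, cfg)

    for mate in (1, 2):
        records = list(_dcs_records(out.dcs, mate))
        if cfg.sscs_policy == "include":
            records.extend(_sscs_records(out.sscs_main, mate))
        seqio.write_fasta(records, f"{out_prefix}_dcs_{mate}.fa")
        if cfg.sscs_policy == "separate":
            seqio.write_fasta(
                _sscs_records(out.sscs_separate, mate), f"{out_prefix}_sscs_{mate}.fa"
            )

    report = dict(out.report)
    report["read_pairs_rejected_short"] = n_rejected
    report["read_pairs_in"] = report["read_pairs_in_families"] + n_rejected
    log.info("pipeline report: %s", report)
    return report
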