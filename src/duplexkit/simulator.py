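"""In silico duplex sequencing.

Generates barcoded paired-end read families from a reference sequence
(optionally spiked with known variants) through a simulated PCR amplification
tree and a sequencing step, together with machine-readable ground truth.
This is both the repository's fixture generator and the engine for the two
simulation studies the package supports: the variant-mixing experiment and
the error-rate/singleton-fraction experiment.

Model
-----
Each fragment is a random interval of the reference (uniform start, uniform
strand).  Both ends are ligated with random 12-bp tags and a constant 5-bp
linker, producing the amplified molecule

    α + linker + insert + revcomp(linker) + revcomp(β)

so that PCR and sequencing errors hit the tags exactly as they hit the
insert — barcode errors, and hence artifactual singleton families, emerge
naturally rather than being modelled separately.

The family's read genealogy is a coalescent simulated backward from the last
PCR cycle: at cycle c, disjoint pairs of open lineages merge with probability
2^-c; the root is forced to split into the two first-cycle daughter
molecules, which are the fragment's physical strands and determine each
read's tag order (αβ vs βα).  On every tree branch spanning k cycles each
base mutates independently with the per-base per-cycle error rate; a
mutation is an indel with probability ``indel_fraction`` (geometric length,
insertion/deletion equiprobable) and otherwise a substitution to a uniformly
chosen different base.  Descendants inherit ancestral mutations; one extra
error round per leaf models the sequencing reaction.  Reads are the first
``read_length`` bases of the final molecule and of its reverse complement,
with every quality fixed at a single Phred value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .seqio import ReadPair, phred_string

log = logging.getLogger(__name__)

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def random_reference(length: int, rng: np.random.Generator, gc: float = 0.44) -> str:
    """A synthetic random reference sequence with the given GC content."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(_BASES))[rng.choice(4, size=length, p=p)])


# ---------------------------------------------------------------------------
# family-size distribution


@dataclass
class FamilySizeDist:
    """Discrete distribution of reads-per-fragment (family size).

    The built-in default is a discretised log-normal with its mode at nine
    reads — the shape of empirically observed duplex family-size
    distributions — with the singleton mass exposed as a parameter.
    """

    sizes: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=np.int64)
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.sizes.min() < 1:
            raise ValueError("family sizes must be >= 1")
        if not math.isclose(self.probs.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("family-size probabilities must sum to 1")

    @classmethod
    def default(
        cls, singleton_mass: float = 0.012, mode: int = 9, sigma: float = 0.55, max_size: int = 60
    ) -> "FamilySizeDist":
        sizes = np.arange(1, max_size + 1)
        mu = math.log(mode) + sigma**2
        pdf = np.exp(-((np.log(sizes) - mu) ** 2) / (2 * sigma**2)) / sizes
        pdf[0] = 0.0
        probs = pdf / pdf.sum() * (1.0 - singleton_mass)
        probs[0] = singleton_mass
        return cls(sizes, probs)

    @classmethod
    def from_mapping(cls, mapping: dict[int, float]) -> "FamilySizeDist":
        items = sorted(mapping.items())
        return cls(np.array([s for s, _ in items]), np.array([p for _, p in items]))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.choice(self.sizes, size=n, p=self.probs)

    def sample_conditional_ge2(self, n: int, rng: np.random.Generator) -> np.ndarray:
        mask = self.sizes >= 2
        p = self.probs[mask]
        return rng.choice(self.sizes[mask], size=n, p=p / p.sum())


def draw_family_sizes(
    n: int,
    dist: FamilySizeDist,
    rng: np.random.Generator,
    exact_singleton_fraction: Optional[float] = None,
) -> np.ndarray:
    """Draw per-fragment family sizes, optionally with an exact singleton count.

    With ``exact_singleton_fraction`` set, exactly ``round(f*n)`` fragments
    get size 1 and the rest are drawn from the distribution conditioned on
    size >= 2 — the fixed "starting distribution" design of the
    error-rate/singleton experiments.
    """
    if exact_singleton_fraction is None:
        return dist.sample(n, rng)
    k = int(round(exact_singleton_fraction * n))
    sizes = np.concatenate(
        [np.ones(k, dtype=np.int64), dist.sample_conditional_ge2(n - k, rng)]
    )
    rng.shuffle(sizes)
    return sizes


# ---------------------------------------------------------------------------
# configuration and truth records


@dataclass
class SimConfig:
    """Full parameterisation of a simulated duplex run.

    ``per_base_per_cycle_error`` applies at every PCR cycle and once more at
    sequencing; ``read_length`` is the total read length including the 12-bp
    tag and the linker.
    """

    fragment_length: int = 600
    read_length: int = 250
    tag_len: int = 12
    linker: str = "TGACT"
    pcr_cycles: int = 30
    per_base_per_cycle_error: float = 0.001
    indel_fraction_of_errors: float = 0.15
    indel_extension_prob: float = 0.3
    fixed_phred: int = 40
    family_size_dist: FamilySizeDist = field(default_factory=FamilySizeDist.default)
    exact_singleton_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        for p in (
            self.per_base_per_cycle_error,
            self.indel_fraction_of_errors,
            self.indel_extension_prob,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} out of [0, 1]")
        if self.read_length > self.fragment_length + self.tag_len + len(self.linker):
            raise ValueError("read_length exceeds the tagged molecule length")

    @property
    def payload_length(self) -> int:
        """Insert bases carried by each read after tag and linker."""
        return self.read_length - self.tag_len - len(self.linker)


@dataclass
class FragmentTruth:
    """Ground truth for one simulated fragment."""

    fragment_id: int
    source: str
    start: int  # 0-based, inclusive, on the source reference
    end: int  # exclusive
    strand: str  # '+' or '-'
    alpha: str
    beta: str
    canonical: str
    family_size: int
    n_ab: int
    n_ba: int


@dataclass
class SimResult:
    pairs: list[ReadPair]
    fragments: list[FragmentTruth]


# ---------------------------------------------------------------------------
# reference mutation (variant spiking)


def mutate_reference(
    ref: str,
    n_sites: int = 21,
    min_spacing: int = 600,
    rng: np.random.Generator | None = None,
) -> tuple[str, list[tuple[int, str, str]]]:
    """Insert random substitutions, pairwise (and end) spacing >= min_spacing.

    Returns the mutated sequence and a truth list of ``(pos0, ref, alt)``.
    Positions are sampled uniformly among all placements satisfying the
    spacing constraint via the standard gap-shift construction.
    """
    rng = np.random.default_rng() if rng is None else rng
    L = len(ref)
    if n_sites == 0:
        return ref, []
    # positions p_1 < ... < p_n with p_1 >= s, L-1-p_n >= s, gaps >= s
    slack = (L - 1) - 2 * min_spacing - (n_sites - 1) * min_spacing
    if slack < 0:
        max_feasible = (L - 1 - 2 * min_spacing) // min_spacing + 1
        raise ValueError(
            f"cannot place {n_sites} sites with spacing {min_spacing} on a "
            f"{L}-bp sequence; at most {max(0, max_feasible)} fit"
        )
    offsets = np.sort(rng.choice(slack + 1, size=n_sites, replace=False)) if slack + 1 >= n_sites else np.zeros(n_sites, dtype=np.int64)
    positions = min_spacing + offsets + min_spacing * np.arange(n_sites)
    out = list(ref)
    truth = []
    for pos in positions:
        pos = int(pos)
        old = out[pos]
        choices = [b for b in _BASES if b != old]
        new = choices[rng.integers(len(choices))]
        out[pos] = new
        truth.append((pos, old, new))
    return "".join(out), truth


def apply_variants(ref: str, variants: Iterable[tuple[int, str, str]]) -> str:
    out = list(ref)
    for pos, old, new in variants:
        if out[pos] != old:
            raise ValueError(f"reference base at {pos} is {out[pos]}, expected {old}")
        out[pos] = new
    return "".join(out)


# ---------------------------------------------------------------------------
# fragments, PCR tree, errors, reads


def sample_fragments(
    ref_len: int, n: int, fragment_length: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform fragment start positions and strands on a linear reference."""
    if fragment_length > ref_len:
        raise ValueError("fragment longer than reference")
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype="U1")
    starts = rng.integers(0, ref_len - fragment_length + 1, size=n)
    strands = np.where(rng.integers(0, 2, size=n) == 0, "+", "-")
    return starts, strands


@dataclass
class PcrNode:
    """A node of one fragment's amplification genealogy.

    ``split_cycle`` is the PCR cycle at which this molecule came into
    existence; leaves carry the id of the read they are sequenced into.
    """

    split_cycle: int
    children: list["PcrNode"] = field(default_factory=list)
    leaf_id: Optional[int] = None

    def leaves(self) -> list["PcrNode"]:
        if self.leaf_id is not None:
            return [self]
        out = []
        stack = list(self.children)
        while stack:
            node = stack.pop()
            if node.leaf_id is not None:
                out.append(node)
            else:
                stack.extend(node.children)
        return out


@dataclass
class PcrTree:
    """Root of a fragment's genealogy: two first-cycle daughter strands.

    ``daughters[0]`` is the αβ strand and ``daughters[1]`` the βα strand;
    either may be ``None`` when no read descends from it.
    """

    daughters: list[Optional[PcrNode]]

    def leaf_count(self) -> int:
        return sum(len(d.leaves()) for d in self.daughters if d is not None)


def build_pcr_tree(
    family_size: int, pcr_cycles: int, rng: np.random.Generator
) -> PcrTree:
    """Backward coalescent over the PCR cycles for one fragment's reads.

    Starting with ``family_size`` lineages at the final cycle, and moving
    one cycle back at a time, open lineages are shuffled and successive
    disjoint pairs each merge with probability 2^-cycle.  Lineages that
    survive to cycle 1 are attached uniformly to one of the two first-cycle
    daughter strands of the original fragment.
    """
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    lineages = [PcrNode(pcr_cycles, leaf_id=i) for i in range(family_size)]
    for cycle in range(pcr_cycles, 1, -1):
        if len(lineages) < 2:
            break
        p = 2.0 ** (-cycle)
        if p < 1e-12:
            continue
        order = rng.permutation(len(lineages))
        merged: list[PcrNode] = []
        i = 0
        while i < len(order):
            if i + 1 < len(order) and rng.random() < p:
                a, b = lineages[order[i]], lineages[order[i + 1]]
                merged.append(PcrNode(cycle - 1, children=[a, b]))
                i += 2
            else:
                merged.append(lineages[order[i]])
                i += 1
        lineages = merged
    daughters: list[Optional[PcrNode]] = [None, None]
    sides: list[list[PcrNode]] = [[], []]
    for node in lineages:
        sides[int(rng.integers(0, 2))].append(node)
    for side, nodes in enumerate(sides):
        if not nodes:
            continue
        if len(nodes) == 1 and nodes[0].leaf_id is None:
            # already a single subtree rooted at or after cycle 1
            daughters[side] = nodes[0]
        else:
            daughters[side] = PcrNode(1, children=list(nodes))
    return PcrTree(daughters)


def _mutate_once(
    seq: list[str], cfg: SimConfig, rng: np.random.Generator
) -> None:
    """Apply one random error (substitution or indel) in place."""
    if not seq:
        return
    pos = int(rng.integers(len(seq)))
    if rng.random() < cfg.indel_fraction_of_errors:
        length = 1
        while rng.random() < cfg.indel_extension_prob:
            length += 1
        if rng.random() < 0.5:  # insertion
            ins = [_BASES[rng.integers(4)] for _ in range(length)]
            seq[pos:pos] = ins
        else:  # deletion
            del seq[pos : pos + length]
    else:
        old = seq[pos]
        choices = [b for b in _BASES if b != old]
        seq[pos] = choices[rng.integers(len(choices))]


def _mutate_branch(
    seq: list[str], n_cycles: int, cfg: SimConfig, rng: np.random.Generator
) -> None:
    p = cfg.per_base_per_cycle_error
    if p <= 0.0 or n_cycles <= 0 or not seq:
        return
    n_errors = rng.binomial(len(seq) * n_cycles, p)
    for _ in range(n_errors):
        _mutate_once(seq, cfg, rng)


def apply_errors(
    tree: PcrTree, template: str, cfg: SimConfig, rng: np.random.Generator
) -> list[tuple[int, int, str]]:
    """Propagate PCR + sequencing errors down the tree.

    Returns ``(leaf_id, daughter_index, final molecule sequence)`` per read;
    a mutation on a branch is inherited by every descendant leaf, and each
    leaf receives one extra error round for the sequencing reaction.
    """
    out: list[tuple[int, int, str]] = []
    for side, daughter in enumerate(tree.daughters):
        if daughter is None:
            continue
        # iterative DFS carrying (node, parent_cycle, sequence-as-list)
        stack: list[tuple[PcrNode, int, list[str]]] = [(daughter, 0, list(template))]
        while stack:
            node, parent_cycle, seq = stack.pop()
            end_cycle = cfg.pcr_cycles if node.leaf_id is not None else node.split_cycle
            seq = list(seq)
            _mutate_branch(seq, end_cycle - parent_cycle, cfg, rng)
            if node.leaf_id is not None:
                leaf_seq = list(seq)
                _mutate_branch(leaf_seq, 1, cfg, rng)  # sequencing round
                out.append((node.leaf_id, side, "".join(leaf_seq)))
            else:
                for child in node.children:
                    stack.append((child, node.split_cycle, seq))
    out.sort(key=lambda t: t[0])
    return out


def tagged_molecule(insert: str, alpha: str, beta: str, linker: str) -> str:
    """The amplified molecule: α + linker + insert + rc(linker) + rc(β)."""
    return alpha + linker + insert + revcomp(linker) + revcomp(beta)


def emit_reads(
    leaves: Sequence[tuple[int, int, str]],
    fragment_id: int,
    read_length: int,
    fixed_phred: int,
) -> tuple[list[ReadPair], int, int]:
    """Paired reads from the final molecules of one fragment's leaves.

    Reads are the first ``read_length`` bases of the molecule (daughter-1
    leaves: mate 1, tag order αβ) and of its reverse complement; daughter-2
    leaves swap the two, giving tag order βα.  Molecules shorter than
    ``read_length`` yield correspondingly truncated reads.
    """
    pairs: list[ReadPair] = []
    n_ab = n_ba = 0
    for leaf_id, side, mol in leaves:
        fwd = mol[:read_length]
        rev = revcomp(mol)[:read_length]
        if len(mol) < read_length:
            log.debug("fragment %d leaf %d: molecule shorter than read length", fragment_id, leaf_id)
        if side == 0:
            seq1, seq2 = fwd, rev
            n_ab += 1
        else:
            seq1, seq2 = rev, fwd
            n_ba += 1
        name = f"frag{fragment_id}-r{leaf_id}"
        pairs.append(
            ReadPair(
                name,
                seq1,
                phred_string([fixed_phred] * len(seq1)),
                seq2,
                phred_string([fixed_phred] * len(seq2)),
            )
        )
    return pairs, n_ab, n_ba


def random_tag(tag_len: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=tag_len))


def simulate_run(
    cfg: SimConfig,
    sources: Sequence[tuple[str, str, int]],
    seed: int | np.random.Generator,
    family_sizes: Optional[np.ndarray] = None,
) -> SimResult:
    """Simulate a duplex experiment over one or more reference sources.

    ``sources`` is a list of ``(name, sequence, n_fragments)``; a 1:10,000
    spike-in mixture, for example, is two sources with the corresponding
    fragment counts.  Fully reproducible from ``seed``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_total = sum(n for _, _, n in sources)
    if family_sizes is None:
        family_sizes = draw_family_sizes(
            n_total, cfg.family_size_dist, rng, cfg.exact_singleton_fraction
        )
    elif len(family_sizes) != n_total:
        raise ValueError("family_sizes length must equal the total fragment count")

    pairs: list[ReadPair] = []
    fragments: list[FragmentTruth] = []
    fid = 0
    for name, ref, n in sources:
        starts, strands = sample_fragments(len(ref), n, cfg.fragment_length, rng)
        for start, strand in zip(starts, strands):
            start = int(start)
            end = start + cfg.fragment_length
            insert = ref[start:end]
            if strand == "-":
                insert = revcomp(insert)
            alpha = random_tag(cfg.tag_len, rng)
            beta = random_tag(cfg.tag_len, rng)
            size = int(family_sizes[fid])
            tree = build_pcr_tree(size, cfg.pcr_cycles, rng)
            leaves = apply_errors(tree, tagged_molecule(insert, alpha, beta, cfg.linker), cfg, rng)
            fam_pairs, n_ab, n_ba = emit_reads(leaves, fid, cfg.read_length, cfg.fixed_phred)
            pairs.extend(fam_pairs)
            canonical = alpha + beta if alpha <= beta else beta + alpha
            fragments.append(
                FragmentTruth(
                    fid, name, start, end, strand, alpha, beta, canonical, size, n_ab, n_ba
                )
            )
            fid += 1
    return SimResult(pairs, fragments)


# ---------------------------------------------------------------------------
# truth I/O


def write_truth_fragments(fragments: Sequence[FragmentTruth], path) -> None:
    from .seqio import open_text

    cols = (
        "fragment_id\tsource\tstart\tend\tstrand\talpha\tbeta\tcanonical\t"
        "family_size\tn_ab\tn_ba\n"
    )
    with open_text(path, "wt") as fh:
        fh.write(cols)
        for f in fragments:
            fh.write(
                f"{f.fragment_id}\t{f.source}\t{f.start}\t{f.end}\t{f.strand}\t"
                f"{f.alpha}\t{f.beta}\t{f.canonical}\t{f.family_size}\t{f.n_ab}\t{f.n_ba}\n"
            )


def write_truth_variants(variants: Sequence[tuple[int, str, str]], path) -> None:
    """Variant truth TSV with 1-based positions (site-table convention)."""
    from .seqio import open_text

    with open_text(path, "wt") as fh:
        fh.write("pos\tref\talt\n")
        for pos0, ref, alt in variants:
            fh.write(f"{pos0 + 1}\t{ref}\t{alt}\n")


# ---------------------------------------------------------------------------
# experiments


def singleton_fraction_experiment(
    error_rates: Sequence[float],
    cfg: SimConfig,
    ref: str,
    n_fragments: int,
    seed: int,
) -> list[dict[str, float]]:
    """Singleton-barcode fraction as a function of the per-stage error rate.

    The realized family-size assignment is drawn once (with an exact
    singleton fraction when the config requests one) and held fixed across
    error rates, so any growth in the singleton fraction is attributable to
    barcode errors alone.  Barcodes are counted per read pair,
    order-normalised, exactly as the family-grouping stage does.
    """
    ss = np.random.SeedSequence(seed)
    size_rng = np.random.default_rng(ss.spawn(1)[0])
    family_sizes = draw_family_sizes(
        n_fragments, cfg.family_size_dist, size_rng, cfg.exact_singleton_fraction
    )
    rows = []
    for rate, child in zip(error_rates, ss.spawn(len(error_rates))):
        run_cfg = replace(cfg, per_base_per_cycle_error=rate)
        result = simulate_run(
            run_cfg,
            [("ref", ref, n_fragments)],
            np.random.default_rng(child),
            family_sizes=family_sizes,
        )
        counts: dict[str, int] = {}
        for pair in result.pairs:
            a = pair.seq1[: cfg.tag_len]
            b = pair.seq2[: cfg.tag_len]
            bc = a + b if a <= b else b + a
            counts[bc] = counts.get(bc, 0) + 1
        n_unique = len(counts)
        n_single = sum(1 for v in counts.values() if v == 1)
        rows.append(
            {
                "error_rate": rate,
                "n_unique_barcodes": n_unique,
                "n_singletons": n_single,
                "singleton_fraction": n_single / n_unique if n_unique else 0.0,
            }
        )
    return rows


def dcs_pileup_from_truth(
    dcs_records: Iterable,
    fragments: Sequence[FragmentTruth],
    cfg: SimConfig,
    sources: dict[str, str],
    flank: int = 8,
):
    """Strand-stratified allele counts from DCSs using fragment ground truth.

    Each DCS is placed by aligning it (edlib, infix mode) against its
    fragment's origin window on the source sequence it was sampled from,
    oriented into reference coordinates via the fragment's strand and tag
    order.  Alignment-based placement tolerates the indels that strand-fixed
    PCR errors leave in consensus sequences, exactly as read mapping would —
    mapping itself is outside this package's scope, but the fragment origin
    is known here, so a windowed pairwise alignment suffices.  Only
    unambiguous A/C/G/T calls on match/mismatch columns are counted.
    Returns a DataFrame with columns (pos, allele, plus, minus); positions
    are 1-based and shared across sources.
    """
    import edlib
    import pandas as pd

    by_bc = {f.canonical: f for f in fragments}
    payload = cfg.payload_length
    counts: dict[tuple[int, str], list[int]] = {}
    for dcs in dcs_records:
        frag = by_bc.get(dcs.canonical_barcode)
        if frag is None or not dcs.seq:
            continue
        source = sources[frag.source]
        # The grouping stage labels tag order lexicographically, so DCS mate
        # 1 reads the insert's 5' end only when alpha <= beta.
        payload_is_5prime = (frag.alpha <= frag.beta) == (dcs.mate == 1)
        if (frag.strand == "+") == payload_is_5prime:
            w_start = max(0, frag.start - flank)
            w_end = min(len(source), frag.start + payload + flank)
            query = dcs.seq
        else:
            w_start = max(0, frag.end - payload - flank)
            w_end = min(len(source), frag.end + flank)
            query = revcomp(dcs.seq)
        target = source[w_start:w_end]
        res = edlib.align(query, target, mode="HW", task="path")
        if res["editDistance"] < 0 or not res["locations"]:
            continue
        nice = edlib.getNiceAlignment(res, query, target)
        pos = w_start + res["locations"][0][0]
        sidx = 0 if frag.strand == "+" else 1
        for qc, tc in zip(nice["query_aligned"], nice["target_aligned"]):
            if tc == "-":  # insertion in the consensus: no reference position
                continue
            if qc != "-" and qc in _BASES:
                key = (pos + 1, qc)
                if key not in counts:
                    counts[key] = [0, 0]
                counts[key][sidx] += 1
            pos += 1
    rows = [
        {"pos": pos, "allele": allele, "plus": c[0], "minus": c[1]}
        for (pos, allele), c in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["pos", "allele", "plus", "minus"])
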