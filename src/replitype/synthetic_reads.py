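"""Synthetic 454-style amplicon runs with full ground truth.

Emulates the study design of a replicated dual-MID amplicon experiment on a
multigene family: pools of 80 amplicons barcoded with 9x9 ten-bp MIDs, ~240 bp
templates between degenerate primers, 4-12 alleles per individual spread over
~6 loci, allele-specific relative amplification efficiencies, and the artefact
classes the downstream filters target (substitutions, 1-2 bp indels, PCR
chimeras, early-PCR error lineages, singleton junk reads).

Every emitted read carries a provenance record, so allele-calling recall and
artefact-detection specificity can be measured exactly.
"""

from __future__ import annotations


from collections import Counter
from dataclasses import dataclass, field

import edlib
import numpy as np

BASES = "ACGT"
STOP_CODONS = {"TAA", "TAG", "TGA"}

# Roche 10-bp extended MID set, the nine tags used in the study design
# (MID numbers 1, 2, 3, 4, 5, 7, 8, 10, 11; pairwise >= 3 differences).
DEFAULT_MIDS = {
    "MID1": "ACGAGTGCGT",
    "MID2": "ACGCTCGACA",
    "MID3": "AGACGCACTC",
    "MID4": "AGCACTGTAG",
    "MID5": "ATCAGACACG",
    "MID7": "CGTGTCTCTA",
    "MID8": "CTCGCGTGTC",
    "MID10": "TCTCTATGCG",
    "MID11": "TGATACGTCT",
}

# MHC class I exon 3 primers (forward DG2 with IUPAC Y degeneracy, reverse GENDG).
FWD_PRIMER = "TTGCGCTCYAGCTCYTTCTGCT"
REV_PRIMER = "TCCCCACAGGTCTCCACAC"

_COMP = str.maketrans("ACGTNRYSWKMBDHV-", "TGCANYRSWMKVHDB-")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class AllelePool:
    """A set of named, mutually distinct allele sequences.

    ``base_length`` is the exon template length; ``insertion_alleles`` carry a
    single in-frame 3-nt insertion (length base_length + 3), mirroring the
    naturally occurring one-codon insertion alleles.
    """

    alleles: tuple[tuple[str, str], ...]
    base_length: int
    insertion_alleles: frozenset[str] = frozenset()

    def __post_init__(self):
        names = [n for n, _ in self.alleles]
        if len(set(names)) != len(names):
            raise ValueError("allele names must be unique")
        seqs = [s for _, s in self.alleles]
        if len(set(seqs)) != len(seqs):
            raise ValueError("allele sequences must be mutually distinct")
        for name, seq in self.alleles:
            want = self.base_length + (3 if name in self.insertion_alleles else 0)
            if len(seq) != want:
                raise ValueError(f"{name}: length {len(seq)} != {want}")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.alleles]

    @property
    def sequences(self) -> dict[str, str]:
        return dict(self.alleles)

    def __len__(self) -> int:
        return len(self.alleles)


@dataclass(frozen=True)
class SimGenotype:
    """One individual's true allele content with per-allele copy numbers.

    Copy numbers come from the locus structure: an allele homozygous at its
    locus contributes two template copies. 1 <= |alleles| <= 2*n_loci.
    """

    sample_id: str
    alleles: frozenset[str]
    n_loci: int
    copy_number: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not 1 <= len(self.alleles) <= 2 * self.n_loci:
            raise ValueError(
                f"{self.sample_id}: {len(self.alleles)} alleles outside "
                f"[1, {2 * self.n_loci}]"
            )
        if not self.copy_number:
            object.__setattr__(self, "copy_number", {a: 1 for a in self.alleles})

    def copies(self, allele: str) -> int:
        return self.copy_number.get(allele, 0)


@dataclass(frozen=True)
class EfficiencyAssignment:
    """Relative amplification efficiency per allele, anchored at a reference."""

    efficiencies: dict[str, float]
    reference: str

    def __post_init__(self):
        if any(e <= 0 for e in self.efficiencies.values()):
            raise ValueError("efficiencies must be > 0")
        if self.efficiencies.get(self.reference) != 1.0:
            raise ValueError("reference allele must be present with efficiency 1")

    def __getitem__(self, allele: str) -> float:
        return self.efficiencies[allele]


@dataclass(frozen=True)
class ErrorModel:
    """Per-read artefact rates for PCR + pyrosequencing.

    substitution_rate   per-base substitution probability
    indel_rate          per-read probability of a single 1-2 bp indel event
    chimera_fraction    fraction of reads that are template-switch chimeras
    singleton_rate      fraction of reads that are heavily mutated junk
                        (expected to be discarded as singletons)
    pcr_lineage_rate    mean number (Poisson) of early-PCR error lineages per
                        amplicon; each lineage is a 1-2 bp variant of one
                        genotype allele amplified to a sizeable fraction of its
                        parent's reads (2^-u, u ~ U(range)), and is specific to
                        its amplicon -- the artefact class the replicate
                        comparison is designed to catch
    high_q/low_q/low_fraction  two-state quality model
    """

    substitution_rate: float = 0.0005
    indel_rate: float = 0.05
    chimera_fraction: float = 0.02
    singleton_rate: float = 0.005
    pcr_lineage_rate: float = 10.0
    lineage_log2_fraction_range: tuple[float, float] = (1.0, 5.0)
    high_q: int = 37
    low_q: int = 12
    low_fraction: float = 0.02

    def __post_init__(self):
        for f in ("substitution_rate", "indel_rate", "chimera_fraction",
                  "singleton_rate", "low_fraction"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f} must be in [0, 1], got {v}")
        if self.pcr_lineage_rate < 0:
            raise ValueError("pcr_lineage_rate must be >= 0")

    @classmethod
    def error_free(cls) -> "ErrorModel":
        return cls(substitution_rate=0.0, indel_rate=0.0, chimera_fraction=0.0,
                   singleton_rate=0.0, pcr_lineage_rate=0.0, low_fraction=0.0)


@dataclass(frozen=True)
class Provenance:
    """Where a read came from: a source allele, a chimera join, or an
    error-derived copy (edits applied on top of the source sequence)."""

    kind: str  # allele | chimera | error | lineage | singleton
    source: str | None = None  # allele name (or lineage id)
    parent_a: str | None = None
    parent_b: str | None = None
    breakpoint: int | None = None
    n_edits: int = 0


@dataclass
class TruthTable:
    """Ground truth for one simulated amplicon.

    Reads are recorded as (count, provenance) groups; ``record_for_read(i)``
    resolves the record of the i-th emitted read, so every read has exactly
    one provenance record while identical reads share storage.
    """

    amplicon_id: str
    genotype: SimGenotype
    efficiencies: dict[str, float]
    records: list[tuple[int, Provenance]] = field(default_factory=list)

    @property
    def n_reads(self) -> int:
        return sum(c for c, _ in self.records)

    def counts_by_kind(self) -> Counter:
        out: Counter = Counter()
        for c, p in self.records:
            out[p.kind] += c
        return out

    def record_for_read(self, index: int) -> Provenance:
        if index < 0:
            raise IndexError(index)
        for c, p in self.records:
            if index < c:
                return p
            index -= c
        raise IndexError("read index beyond n_reads")


@dataclass
class SimAmplicon:
    """A simulated amplicon: template-only reads plus their truth table."""

    amplicon_id: str
    sample_id: str
    replicate: int
    reads: list[str]
    truth: TruthTable


# ---------------------------------------------------------------------------
# pool and population generation


def _random_coding_seq(length: int, rng: np.random.Generator) -> str:
    """Random sequence of full codons with no stop codon in frame 1."""
    codons = []
    while len(codons) * 3 < length:
        c = "".join(BASES[i] for i in rng.integers(0, 4, size=3))
        if c not in STOP_CODONS:
            codons.append(c)
    return "".join(codons)[:length]


def _has_inframe_stop(seq: str) -> bool:
    return any(seq[i:i + 3] in STOP_CODONS for i in range(0, len(seq) - 2, 3))


def _mutate_no_stop(seq: str, n_mut: int, rng: np.random.Generator,
                    max_tries: int = 200) -> str:
    """Apply n_mut substitutions avoiding in-frame stop codons."""
    for _ in range(max_tries):
        s = list(seq)
        pos = rng.choice(len(s), size=min(n_mut, len(s)), replace=False)
        for p in pos:
            s[p] = BASES[(BASES.index(s[p]) + rng.integers(1, 4)) % 4]
        out = "".join(s)
        if not _has_inframe_stop(out):
            return out
    raise RuntimeError("could not place substitutions without a stop codon")


def edit_distance(a: str, b: str, k: int = -1) -> int:
    """Levenshtein distance via edlib; with k >= 0, returns -1 if distance > k."""
    return edlib.align(a, b, task="distance", k=k)["editDistance"]


def make_allele_pool(n_alleles: int, base_length: int, min_pairwise_diff: int,
                     n_insertion_alleles: int, seed: int,
                     divergence: int | None = None,
                     name_prefix: str = "SIM",
                     max_attempts: int = 2000) -> AllelePool:
    """Generate an allele family: a shared ancestor plus per-allele substitutions.

    The family structure (rather than independent random sequences) reproduces
    the ~10 % pairwise divergence of real MHC allele sets, which in turn makes
    chimeric reads collapse into recurrent clusters. ``divergence`` is the
    number of substitutions separating each allele from the ancestor; the
    default scales with length (~5.5 % of sites, 13 at 240 bp).
    """
    if n_alleles < 2:
        raise ValueError("n_alleles must be >= 2")
    if base_length % 3:
        raise ValueError("base_length must be divisible by 3")
    if min_pairwise_diff < 1:
        raise ValueError("min_pairwise_diff must be >= 1")
    if n_insertion_alleles > n_alleles:
        raise ValueError("more insertion alleles than alleles")
    rng = np.random.default_rng(seed)
    if divergence is None:
        divergence = max(min_pairwise_diff, round(0.055 * base_length))
    divergence = min(divergence, base_length)

    ancestor = _random_coding_seq(base_length, rng)
    seqs: list[str] = []
    attempts = 0
    while len(seqs) < n_alleles:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                "could not satisfy pool constraints; parameters over-constrained")
        cand = _mutate_no_stop(ancestor, divergence, rng)
        if all((d := edit_distance(cand, s, k=min_pairwise_diff - 1)) == -1
               for s in seqs):
            seqs.append(cand)

    names = [f"{name_prefix}{i + 1:02d}" for i in range(n_alleles)]
    insertion = set()
    if n_insertion_alleles:
        which = rng.choice(n_alleles, size=n_insertion_alleles, replace=False)
        for i in sorted(which):
            for _ in range(max_attempts):
                codon_at = int(rng.integers(1, base_length // 3)) * 3
                ins = "".join(BASES[j] for j in rng.integers(0, 4, size=3))
                if ins in STOP_CODONS:
                    continue
                cand = seqs[i][:codon_at] + ins + seqs[i][codon_at:]
                if not _has_inframe_stop(cand) and cand not in seqs:
                    seqs[i] = cand
                    insertion.add(names[i])
                    break
            else:
                raise RuntimeError("could not place in-frame insertion")

    return AllelePool(alleles=tuple(zip(names, seqs)), base_length=base_length,
                      insertion_alleles=frozenset(insertion))


def make_population(pool: AllelePool, n_samples: int, n_loci: int,
                    allele_freqs: np.ndarray | None, seed: int,
                    copy_number_one: bool = False) -> list[SimGenotype]:
    """Draw Hardy-Weinberg genotypes at n_loci loci.

    Alleles are assigned to loci round-robin by pool order; ``allele_freqs``
    (one entry per pool allele, or None for uniform) is renormalised within
    each locus. Each locus contributes two draws with replacement, so a
    homozygous locus gives its allele copy number 2 (or 1 with
    ``copy_number_one``, matching the efficiency model's assumption).
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if n_loci > len(pool):
        raise ValueError("n_loci cannot exceed the number of pool alleles")
    rng = np.random.default_rng(seed)
    n = len(pool)
    if allele_freqs is None:
        freqs = np.full(n, 1.0 / n)
    else:
        freqs = np.asarray(allele_freqs, dtype=float)
        if freqs.shape != (n,):
            raise ValueError("allele_freqs must have one entry per allele")
        if (freqs < 0).any():
            raise ValueError("allele_freqs must be non-negative")

    names = pool.names
    loci: list[tuple[list[str], np.ndarray]] = []
    for locus in range(n_loci):
        idx = list(range(locus, n, n_loci))
        f = freqs[idx]
        if f.sum() <= 0:
            raise ValueError(f"locus {locus} has zero total frequency")
        loci.append(([names[i] for i in idx], f / f.sum()))

    genotypes = []
    for s in range(n_samples):
        copies: Counter = Counter()
        for locus_names, locus_freqs in loci:
            draws = rng.choice(len(locus_names), size=2, p=locus_freqs)
            for d in draws:
                copies[locus_names[d]] += 1
        if copy_number_one:
            copies = Counter({a: 1 for a in copies})
        genotypes.append(SimGenotype(
            sample_id=f"S{s + 1:04d}", alleles=frozenset(copies),
            n_loci=n_loci, copy_number=dict(copies)))
    return genotypes


# ---------------------------------------------------------------------------
# amplicon simulation


def _apply_substitutions(seq: str, n_sub: int, rng: np.random.Generator) -> str:
    s = list(seq)
    for p in rng.choice(len(s), size=min(n_sub, len(s)), replace=False):
        s[p] = BASES[(BASES.index(s[p]) + rng.integers(1, 4)) % 4]
    return "".join(s)


def _apply_indel(seq: str, rng: np.random.Generator) -> str:
    width = int(rng.integers(1, 3))  # 1 or 2 bp
    pos = int(rng.integers(0, len(seq)))
    if rng.random() < 0.5 and len(seq) > width:
        return seq[:pos] + seq[pos + width:]
    ins = "".join(BASES[i] for i in rng.integers(0, 4, size=width))
    return seq[:pos] + ins + seq[pos:]


def _lineage_variant(seq: str, rng: np.random.Generator) -> tuple[str, int]:
    """A 1-2 bp edit of the parent sequence (early-PCR error lineage)."""
    n_edits = int(rng.integers(1, 3))
    out = seq
    for _ in range(n_edits):
        if rng.random() < 0.5:
            out = _apply_substitutions(out, 1, rng)
        else:
            out = _apply_indel(out, rng)
    return out, n_edits


def simulate_amplicon(genotype: SimGenotype, eff: EfficiencyAssignment,
                      n_reads: int, error: ErrorModel, seed: int,
                      sequences: AllelePool | dict[str, str],
                      amplicon_id: str = "amp", sample_id: str | None = None,
                      replicate: int = 1) -> SimAmplicon:
    """Simulate one amplicon's reads.

    Error-free reads are multinomial over genotype alleles with probabilities
    p_i = c_i e_i / sum_j c_j e_j (copy number x relative efficiency).
    Chimeras join a prefix of one error-free parent read with the suffix of a
    different parent, parents drawn proportionally to parent read frequency
    and breakpoints uniform over internal positions. Early-PCR lineages add
    recurrent 1-2 bp variants of one allele at a sizeable fraction of its
    reads. Per-read substitution/indel errors are then overlaid.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    seq_of = sequences.sequences if isinstance(sequences, AllelePool) else sequences
    alleles = sorted(genotype.alleles)
    for a in alleles:
        if a not in eff.efficiencies:
            raise KeyError(f"allele {a} missing from efficiency table")
        if a not in seq_of:
            raise KeyError(f"allele {a} has no sequence")
    rng = np.random.default_rng(seed)
    sample_id = sample_id or genotype.sample_id

    weights = np.array([genotype.copies(a) * eff[a] for a in alleles],
                       dtype=float)

    # early-PCR lineages: extra templates with weight fraction * parent weight
    lin_entries: list[tuple[str, str, int, float]] = []  # (seq, parent, edits, w)
    if error.pcr_lineage_rate > 0:
        n_lin = int(rng.poisson(error.pcr_lineage_rate))
        lo, hi = error.lineage_log2_fraction_range
        p_parent = weights / weights.sum()
        for _ in range(n_lin):
            pi = int(rng.choice(len(alleles), p=p_parent))
            frac = 2.0 ** (-rng.uniform(lo, hi))
            var, n_edits = _lineage_variant(seq_of[alleles[pi]], rng)
            lin_entries.append((var, alleles[pi], n_edits, frac * weights[pi]))

    # read composition: chimera / singleton flags first, rest multinomial
    n_chim = rng.binomial(n_reads, error.chimera_fraction)
    n_single = rng.binomial(n_reads - n_chim, error.singleton_rate)
    n_body = n_reads - n_chim - n_single

    all_w = np.concatenate([weights, [w for *_, w in lin_entries]]) \
        if lin_entries else weights
    body_counts = rng.multinomial(n_body, all_w / all_w.sum())

    truth = TruthTable(amplicon_id=amplicon_id, genotype=genotype,
                       efficiencies={a: eff[a] for a in alleles})
    reads: list[str] = []

    def emit(seq: str, count: int, prov: Provenance) -> None:
        if count <= 0:
            return
        reads.extend([seq] * count)
        truth.records.append((count, prov))

    def emit_with_seq_errors(seq: str, count: int, base_prov: Provenance) -> None:
        """Split count into clean copies and per-read substitution/indel errors."""
        if count <= 0:
            return
        n_sub = rng.binomial(len(seq), error.substitution_rate, size=count) \
            if error.substitution_rate > 0 else np.zeros(count, dtype=int)
        has_indel = rng.random(count) < error.indel_rate \
            if error.indel_rate > 0 else np.zeros(count, dtype=bool)
        clean = int(np.sum((n_sub == 0) & ~has_indel))
        emit(seq, clean, base_prov)
        for k, ind in zip(n_sub, has_indel):
            if k == 0 and not ind:
                continue
            mutated = _apply_substitutions(seq, int(k), rng) if k else seq
            if ind:
                mutated = _apply_indel(mutated, rng)
            emit(mutated, 1, Provenance(
                kind="error", source=base_prov.source,
                parent_a=base_prov.parent_a, parent_b=base_prov.parent_b,
                breakpoint=base_prov.breakpoint,
                n_edits=int(k) + (1 if ind else 0)))

    # alleles and lineages
    for i, a in enumerate(alleles):
        emit_with_seq_errors(seq_of[a], int(body_counts[i]),
                             Provenance(kind="allele", source=a))
    for j, (var, parent, n_edits, _) in enumerate(lin_entries):
        emit_with_seq_errors(var, int(body_counts[len(alleles) + j]),
                             Provenance(kind="lineage", source=parent,
                                        n_edits=n_edits))

    # chimeras: parents drawn proportionally to error-free allele read counts
    if n_chim:
        allele_counts = body_counts[:len(alleles)].astype(float)
        if allele_counts.sum() == 0 or len(alleles) < 2:
            n_single += n_chim  # cannot form chimeras; degrade to junk
        else:
            p = allele_counts / allele_counts.sum()
            for _ in range(n_chim):
                ia, ib = rng.choice(len(alleles), size=2, replace=False,
                                    p=p) if (p > 0).sum() >= 2 else (0, 1)
                sa, sb = seq_of[alleles[ia]], seq_of[alleles[ib]]
                k = int(rng.integers(1, min(len(sa), len(sb))))
                emit_with_seq_errors(
                    sa[:k] + sb[k:], 1,
                    Provenance(kind="chimera", parent_a=alleles[ia],
                               parent_b=alleles[ib], breakpoint=k))

    # singleton junk: heavily mutated copies, effectively unique
    for _ in range(n_single):
        src = alleles[int(rng.integers(0, len(alleles)))]
        junk = _apply_substitutions(seq_of[src], 3, rng)
        emit(junk, 1, Provenance(kind="singleton", source=src, n_edits=3))

    assert truth.n_reads == n_reads
    return SimAmplicon(amplicon_id=amplicon_id, sample_id=sample_id,
                       replicate=replicate, reads=reads, truth=truth)


# ---------------------------------------------------------------------------
# run layout and serialisation


@dataclass(frozen=True)
class MidAssignment:
    pool: int
    sample_id: str
    replicate: int
    fwd_mid: str  # MID name
    rev_mid: str


def design_layout(sample_ids: list[str], n_pools: int = 8,
                  mids: dict[str, str] | None = None) -> list[MidAssignment]:
    """Assign each sample's two replicates to different pools with different
    (forward, reverse) MID combinations, unique within each pool.

    With 9 forward x 9 reverse MIDs there are 81 combinations per pool, enough
    for pools of 80 amplicons.
    """
    mids = mids or DEFAULT_MIDS
    names = list(mids)
    pool_combos = {p: [(f, r) for f in names for r in names]
                   for p in range(n_pools)}
    per_pool_next = [0] * n_pools
    assignments: list[MidAssignment] = []
    by_sample: dict[str, tuple[str, str]] = {}
    for s, sid in enumerate(sample_ids):
        for rep in (1, 2):
            pool = (s + (rep - 1)) % n_pools
            combos = pool_combos[pool]
            idx = per_pool_next[pool]
            if idx >= len(combos):
                raise ValueError(f"pool {pool} overflows the MID combinations")
            if rep == 2 and by_sample.get(sid) == combos[idx]:
                # replicates must differ in MID combination: take the next
                # combination and keep the conflicted one available
                if idx + 1 >= len(combos):
                    raise ValueError(
                        f"pool {pool} overflows the MID combinations")
                combos[idx], combos[idx + 1] = combos[idx + 1], combos[idx]
            combo = combos[idx]
            per_pool_next[pool] += 1
            by_sample.setdefault(sid, combo)
            assignments.append(MidAssignment(pool=pool, sample_id=sid,
                                             replicate=rep, fwd_mid=combo[0],
                                             rev_mid=combo[1]))
    return assignments


_IUPAC_CHOICES = {
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def _instantiate_primer(primer: str, rng: np.random.Generator) -> str:
    """One concrete realisation of a degenerate primer (as in a synthesis
    pool, each physical molecule carries one base at each degenerate site)."""
    return "".join(c if c in BASES
                   else _IUPAC_CHOICES[c][rng.integers(0, len(_IUPAC_CHOICES[c]))]
                   for c in primer)


def _quality_string(length: int, error: ErrorModel,
                    rng: np.random.Generator) -> str:
    low = rng.random(length) < error.low_fraction
    quals = np.where(low, error.low_q, error.high_q) + 33
    return "".join(chr(int(q)) for q in quals)


def write_run(amplicons: list[SimAmplicon], mid_table: list[MidAssignment],
              primers: tuple[str, str], output_dir, error: ErrorModel,
              seed: int, mids: dict[str, str] | None = None,
              key: str = "") -> dict[str, str]:
    """Serialise a simulated run: one FASTQ per pool plus truth/MID-map TSVs.

    Each read is written as
    ``key + fwd_MID + fwd_primer + template + rc(rev_primer) + rc(rev_MID)``
    with two-state per-base qualities. Returns the mapping of written files.
    Deterministic for fixed seed.
    """
    import os

    mids = mids or DEFAULT_MIDS
    fwd_primer, rev_primer = primers
    os.makedirs(output_dir, exist_ok=True)
    assign = {(m.sample_id, m.replicate): m for m in mid_table}
    if len(assign) != len(mid_table):
        raise ValueError("duplicate (sample, replicate) in MID table")
    for pool in {m.pool for m in mid_table}:
        combos = [(m.fwd_mid, m.rev_mid) for m in mid_table if m.pool == pool]
        if len(set(combos)) != len(combos):
            raise ValueError(f"duplicate MID pair within pool {pool}")

    rng = np.random.default_rng(seed)
    files: dict[str, str] = {}
    handles = {}
    pools = sorted({m.pool for m in mid_table})
    for pool in pools:
        path = os.path.join(output_dir, f"pool{pool}.fastq")
        handles[pool] = open(path, "w")
        files[f"pool{pool}"] = path

    truth_path = os.path.join(output_dir, "truth.tsv")
    with open(truth_path, "w") as truth_fh:
        truth_fh.write("read_id\tamplicon_id\tsample_id\treplicate\t"
                       "provenance\tsource\tparent_a\tparent_b\tbreakpoint\n")
        for amp in amplicons:
            m = assign[(amp.sample_id, amp.replicate)]
            fh = handles[m.pool]
            i = 0
            for count, prov in amp.truth.records:
                for _ in range(count):
                    rid = f"{amp.amplicon_id}_{i:06d}"
                    seq = (key + mids[m.fwd_mid]
                           + _instantiate_primer(fwd_primer, rng)
                           + amp.reads[i]
                           + revcomp(_instantiate_primer(rev_primer, rng))
                           + revcomp(mids[m.rev_mid]))
                    fh.write(f"@{rid}\n{seq}\n+\n"
                             f"{_quality_string(len(seq), error, rng)}\n")
                    truth_fh.write(
                        f"{rid}\t{amp.amplicon_id}\t{amp.sample_id}\t"
                        f"{amp.replicate}\t{prov.kind}\t{prov.source or ''}\t"
                        f"{prov.parent_a or ''}\t{prov.parent_b or ''}\t"
                        f"{'' if prov.breakpoint is None else prov.breakpoint}\n")
                    i += 1
    for fh in handles.values():
        fh.close()
    files["truth"] = truth_path

    mid_path = os.path.join(output_dir, "mids.tsv")
    with open(mid_path, "w") as fh:
        fh.write("pool\tsample_id\treplicate\tfwd_MID\trev_MID\n")
        for m in mid_table:
            fh.write(f"{m.pool}\t{m.sample_id}\t{m.replicate}\t"
                     f"{m.fwd_mid}\t{m.rev_mid}\n")
    files["mids"] = mid_path
    return files


def negative_binomial_depths(n: int, mean: float, dispersion: float,
                             rng: np.random.Generator,
                             minimum: int = 2) -> np.ndarray:
    """Reads-per-amplicon draws: NB with given mean and shape (dispersion k)."""
    lam = rng.gamma(dispersion, mean / dispersion, size=n)
    return np.maximum(rng.poisson(lam), minimum)


@dataclass
class SimulatedRun:
    """A full simulated study: genotypes, efficiencies and all amplicons."""

    pool: AllelePool
    genotypes: list[SimGenotype]
    efficiencies: EfficiencyAssignment
    amplicons: list[SimAmplicon]
    layout: list[MidAssignment]
    error: ErrorModel

    def truth_genotypes(self) -> dict[str, frozenset[str]]:
        return {g.sample_id: g.alleles for g in self.genotypes}


def simulate_run(n_samples: int = 320, n_alleles: int = 22,
                 base_length: int = 240, n_loci: int = 6,
                 n_insertion_alleles: int = 2, min_pairwise_diff: int = 2,
                 efficiency_range: tuple[float, float] = (0.5, 2.0),
                 mean_reads: float = 1430.0, dispersion: float = 5.0,
                 error: ErrorModel | None = None, n_pools: int = 8,
                 seed: int = 0,
                 genotypes: list[SimGenotype] | None = None,
                 efficiencies: EfficiencyAssignment | None = None,
                 pool: AllelePool | None = None) -> SimulatedRun:
    """Simulate a replicated study at the published design scale by default:
    320 samples x 2 replicates in 8 pools of 80, 22-allele pool, ~6 loci,
    mean 1,430 reads per amplicon.

    A master seed feeds named substreams (pool, genotypes, efficiencies,
    depths, reads) so each component is independently reproducible.
    """
    error = error or ErrorModel()
    ss = np.random.SeedSequence(seed)
    s_pool, s_geno, s_eff, s_depth, s_reads = ss.spawn(5)

    if pool is None:
        pool = make_allele_pool(n_alleles, base_length, min_pairwise_diff,
                                n_insertion_alleles,
                                seed=int(s_pool.generate_state(1)[0] >> 33))
    if genotypes is None:
        genotypes = make_population(pool, n_samples, n_loci, None,
                                    seed=int(s_geno.generate_state(1)[0] >> 33))
    if efficiencies is None:
        rng_e = np.random.default_rng(s_eff)
        lo, hi = efficiency_range
        effs = {name: float(rng_e.uniform(lo, hi)) for name in pool.names}
        effs[pool.names[0]] = 1.0
        efficiencies = EfficiencyAssignment(efficiencies=effs,
                                            reference=pool.names[0])

    layout = design_layout([g.sample_id for g in genotypes], n_pools=n_pools)
    rng_d = np.random.default_rng(s_depth)
    depths = negative_binomial_depths(len(layout), mean_reads, dispersion,
                                      rng_d)
    read_seeds = np.random.default_rng(s_reads).integers(
        0, 2**31 - 1, size=len(layout))

    seq_of = pool.sequences
    geno_of = {g.sample_id: g for g in genotypes}
    amplicons = []
    for i, m in enumerate(layout):
        amp = simulate_amplicon(
            geno_of[m.sample_id], efficiencies, int(depths[i]), error,
            seed=int(read_seeds[i]), sequences=seq_of,
            amplicon_id=f"{m.sample_id}_r{m.replicate}",
            sample_id=m.sample_id, replicate=m.replicate)
        amplicons.append(amp)
    return SimulatedRun(pool=pool, genotypes=genotypes,
                        efficiencies=efficiencies, amplicons=amplicons,
                        layout=layout, error=error)
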