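"""Alignment-level diversity, recombination and selection statistics.

Operates on gapped nucleotide alignments of allele sets: variable sites,
minimum mutation counts, nucleotide diversity, Watterson's theta, the
Hudson-Kaplan four-gamete lower bound on recombination events, translation
with unique-protein collapsing, and Nei-Gojobori (1986) synonymous /
non-synonymous distances with Jukes-Cantor correction, computed over the full
exon or over a peptide-binding-region (PBR) codon partition supplied by the
user.

Gap handling follows the conventions of the standard tools: alignment-wide
statistics use complete deletion (any column containing a gap is excluded),
pairwise dN/dS skips codon pairs in which either codon contains a gap.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from scipy import stats as sps

CODON_TABLE = dict(standard_dna_table.forward_table)
STOP_CODONS = set(standard_dna_table.stop_codons)


def translate_codon(codon: str) -> str:
    if codon == "---":
        return "-"
    if codon in STOP_CODONS:
        return "*"
    return CODON_TABLE[codon]


@dataclass
class AlleleAlignment:
    """Equal-length aligned nucleotide sequences (gaps '-'), codon frame 0."""

    names: list[str]
    sequences: list[str]
    frame: int = 0

    def __post_init__(self):
        if len(self.names) != len(self.sequences):
            raise ValueError("names/sequences length mismatch")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError("alignment rows must have equal length")
        bad = set("".join(self.sequences)) - set("ACGT-")
        if bad:
            raise ValueError(f"unexpected characters in alignment: {bad}")

    def _check_frame(self):
        # codon-based operations need a full reading frame
        if (self.length - self.frame) % 3:
            raise ValueError("aligned length not divisible by 3 from frame")

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @classmethod
    def from_fasta(cls, path, frame: int = 0) -> "AlleleAlignment":
        from Bio import SeqIO

        names, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            names.append(rec.id)
            seqs.append(str(rec.seq).upper())
        return cls(names=names, sequences=seqs, frame=frame)

    def matrix(self) -> np.ndarray:
        return np.array([list(s) for s in self.sequences])

    def gap_free_columns(self) -> np.ndarray:
        return ~(self.matrix() == "-").any(axis=0)


@dataclass(frozen=True)
class DiversityStats:
    n: int
    L: int  # gap-free sites analysed
    S: int  # variable (segregating) sites
    eta: int  # minimum number of mutations
    pi: float  # nucleotide diversity per site
    k: float  # mean pairwise differences
    theta_w: float  # Watterson estimator (eta-based by default)
    rm: int  # Hudson-Kaplan four-gamete minimum


@dataclass(frozen=True)
class SitePartition:
    """1-based codon indices of the peptide binding region."""

    pbr_codons: tuple[int, ...]

    def __post_init__(self):
        if len(set(self.pbr_codons)) != len(self.pbr_codons):
            raise ValueError("duplicate PBR codon indices")
        if any(i < 1 for i in self.pbr_codons):
            raise ValueError("codon indices are 1-based")

    @classmethod
    def from_file(cls, path) -> "SitePartition":
        with open(path) as fh:
            idx = tuple(int(line.strip()) for line in fh if line.strip())
        return cls(pbr_codons=idx)


@dataclass(frozen=True)
class DnDsResult:
    partition: str  # full | PBR | nonPBR
    mean_dn: float
    mean_ds: float
    ratio: float
    dn_pairs: np.ndarray = field(repr=False, default=None)
    ds_pairs: np.ndarray = field(repr=False, default=None)
    mannwhitney_p: float = float("nan")


# ---------------------------------------------------------------------------
# nucleotide diversity


def diversity(aln: AlleleAlignment, theta_from: str = "eta") -> DiversityStats:
    """Alignment-wide diversity under complete deletion of gapped columns.

    S counts columns with >= 2 states, eta sums (states - 1) per column
    (the minimum mutation count), k is the mean pairwise difference over all
    sequence pairs, pi = k / L, and Watterson's theta is eta / a_{n-1}
    (or S / a_{n-1} with ``theta_from='S'``).
    """
    if aln.n < 2:
        raise ValueError("diversity requires >= 2 sequences")
    mat = aln.matrix()[:, aln.gap_free_columns()]
    n, L = mat.shape
    n_states = np.array([len(set(mat[:, j])) for j in range(L)])
    S = int((n_states >= 2).sum())
    eta = int((n_states - 1).sum())

    pair_diffs = [np.sum(mat[i] != mat[j])
                  for i, j in itertools.combinations(range(n), 2)]
    k = float(np.mean(pair_diffs))
    a_n = float(sum(1.0 / i for i in range(1, n)))
    base = eta if theta_from == "eta" else S
    return DiversityStats(n=n, L=L, S=S, eta=eta, pi=k / L, k=k,
                          theta_w=base / a_n,
                          rm=four_gamete_rm(aln))


def four_gamete_rm(aln: AlleleAlignment) -> int:
    """Hudson-Kaplan minimum number of recombination events.

    Finds all pairs of biallelic gap-free sites exhibiting all four gametes,
    reduces the incompatible intervals to the minimal set, and counts the
    maximum number of non-overlapping intervals (each must contain at least
    one recombination event).
    """
    mat = aln.matrix()[:, aln.gap_free_columns()]
    n, L = mat.shape
    biallelic = [j for j in range(L) if len(set(mat[:, j])) == 2]
    intervals = []
    for a, b in itertools.combinations(biallelic, 2):
        gametes = {(x, y) for x, y in zip(mat[:, a], mat[:, b])}
        if len(gametes) == 4:
            intervals.append((a, b))
    return _min_recombinations(intervals)


def _min_recombinations(intervals: list[tuple[int, int]]) -> int:
    """Maximum set of pairwise disjoint open intervals (i, j): each needs its
    own recombination event, and this greedy count is the HK85 lower bound."""
    if not intervals:
        return 0
    events = 0
    last_right = -1
    for left, right in sorted(intervals, key=lambda iv: iv[1]):
        if left >= last_right:  # open intervals (left, right) are disjoint
            events += 1
            last_right = right
    return events


# ---------------------------------------------------------------------------
# Nei-Gojobori 1986 with Jukes-Cantor correction


def _syn_fraction(codon: str, pos: int) -> float:
    """Fraction of the three possible changes at ``pos`` that are synonymous.

    Changes producing stop codons count as non-synonymous.
    """
    aa = CODON_TABLE[codon]
    syn = 0
    for b in "ACGT":
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1:]
        if alt not in STOP_CODONS and CODON_TABLE[alt] == aa:
            syn += 1
    return syn / 3.0


def _codon_sites(codon: str) -> float:
    """Synonymous sites of one codon (non-synonymous = 3 - synonymous)."""
    return sum(_syn_fraction(codon, p) for p in range(3))


def _pathway_counts(c1: str, c2: str) -> tuple[float, float] | None:
    """(synonymous, non-synonymous) differences between two codons, averaged
    over all minimal substitution pathways that avoid stop codons."""
    diff_pos = [p for p in range(3) if c1[p] != c2[p]]
    if not diff_pos:
        return 0.0, 0.0
    totals = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        sd = nd = 0
        ok = True
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            if CODON_TABLE[cur] == CODON_TABLE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            totals.append((sd, nd))
    if not totals:
        return None  # all pathways blocked by stop codons
    sd = float(np.mean([t[0] for t in totals]))
    nd = float(np.mean([t[1] for t in totals]))
    return sd, nd


def jukes_cantor(p: float) -> float:
    """JC69 distance correction; undefined (NaN) at p >= 3/4."""
    if p >= 0.75:
        return float("nan")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def ng_site_counts(seq1: str, seq2: str) -> tuple[float, float, float, float]:
    """NG86 raw counts between two in-frame sequences:
    (synonymous sites, non-synonymous sites, synonymous differences,
    non-synonymous differences).

    Site counts are averaged between the two sequences; codon pairs containing
    a gap are skipped; multi-step codon differences are averaged over all
    minimal pathways excluding those through stop codons.
    """
    if len(seq1) != len(seq2):
        raise ValueError("sequences must be aligned to equal length")
    if len(seq1) % 3:
        raise ValueError("length must be divisible by 3")
    s_sites = n_sites = sd = nd = 0.0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i:i + 3], seq2[i:i + 3]
        if "-" in c1 or "-" in c2:
            continue
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            raise ValueError(f"in-frame stop codon at nucleotide {i + 1}")
        s1, s2 = _codon_sites(c1), _codon_sites(c2)
        s_sites += (s1 + s2) / 2.0
        n_sites += 3.0 - (s1 + s2) / 2.0
        counts = _pathway_counts(c1, c2)
        if counts is None:
            continue
        sd += counts[0]
        nd += counts[1]
    return s_sites, n_sites, sd, nd


def nei_gojobori(seq1: str, seq2: str) -> tuple[float, float]:
    """(dN, dS) between two in-frame coding sequences (NG86 + JC correction)."""
    s_sites, n_sites, sd, nd = ng_site_counts(seq1, seq2)
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    return jukes_cantor(pn), jukes_cantor(ps)


def _codon_slice(seq: str, codon_indices: list[int]) -> str:
    return "".join(seq[3 * (c - 1):3 * c] for c in codon_indices)


def dnds_summary(aln: AlleleAlignment,
                 partition: SitePartition | None = None) -> list[DnDsResult]:
    """Mean pairwise dN and dS per codon partition, with a two-sided
    Mann-Whitney U test comparing the off-diagonal dN and dS values.

    Partitions are ``full`` plus, when a PBR partition is given, ``PBR`` and
    ``nonPBR``. The rank test ignores the non-independence of pairwise
    distances, as is conventional for these comparisons.
    """
    aln._check_frame()
    n_codons = (aln.length - aln.frame) // 3
    parts: dict[str, list[int]] = {"full": list(range(1, n_codons + 1))}
    if partition is not None:
        pbr = [c for c in partition.pbr_codons]
        if not pbr:
            raise ValueError("empty PBR partition")
        if max(pbr) > n_codons:
            raise ValueError("PBR codon index beyond alignment")
        parts["PBR"] = sorted(pbr)
        parts["nonPBR"] = [c for c in range(1, n_codons + 1)
                           if c not in set(pbr)]
        if not parts["nonPBR"]:
            raise ValueError("empty non-PBR partition")

    body = [s[aln.frame:] for s in aln.sequences]
    results = []
    for name, codons in parts.items():
        dn_list, ds_list = [], []
        for i, j in itertools.combinations(range(aln.n), 2):
            dn, ds = nei_gojobori(_codon_slice(body[i], codons),
                                  _codon_slice(body[j], codons))
            if not (np.isnan(dn) or np.isnan(ds)):
                dn_list.append(dn)
                ds_list.append(ds)
        dn_arr, ds_arr = np.array(dn_list), np.array(ds_list)
        if len(dn_arr) == 0:
            # every pair saturated (p >= 3/4): distances undefined
            results.append(DnDsResult(partition=name, mean_dn=float("nan"),
                                      mean_ds=float("nan"),
                                      ratio=float("nan"), dn_pairs=dn_arr,
                                      ds_pairs=ds_arr))
            continue
        mean_dn, mean_ds = float(dn_arr.mean()), float(ds_arr.mean())
        if np.allclose(dn_arr, dn_arr[0]) and np.allclose(ds_arr, ds_arr[0]) \
                and np.isclose(dn_arr[0], ds_arr[0]):
            p = 1.0  # identical constant samples: no evidence either way
        else:
            p = float(sps.mannwhitneyu(dn_arr, ds_arr,
                                       alternative="two-sided").pvalue)
        results.append(DnDsResult(
            partition=name, mean_dn=mean_dn, mean_ds=mean_ds,
            ratio=mean_dn / mean_ds if mean_ds > 0 else float("nan"),
            dn_pairs=dn_arr, ds_pairs=ds_arr, mannwhitney_p=p))
    return results


# ---------------------------------------------------------------------------
# translation


@dataclass(frozen=True)
class ProteinSummary:
    names: list[str]
    proteins: list[str]  # aligned amino-acid rows (gaps '-')
    n_unique: int
    variable_sites: int
    aa_changes: int


def translate_and_collapse(aln: AlleleAlignment) -> ProteinSummary:
    """Translate in frame and summarise protein-level variation.

    Gap codons ('---') become '-'; an internal stop raises an error naming
    the offending sequence. Variable sites count columns with >= 2 distinct
    residues (gaps ignored); amino-acid changes sum (distinct residues - 1)
    per column.
    """
    aln._check_frame()
    proteins = []
    for name, seq in zip(aln.names, aln.sequences):
        body = seq[aln.frame:]
        aas = []
        for i in range(0, len(body), 3):
            codon = body[i:i + 3]
            if "-" in codon and codon != "---":
                raise ValueError(f"{name}: out-of-frame gap at codon {i // 3 + 1}")
            aa = translate_codon(codon)
            if aa == "*":
                raise ValueError(f"{name}: internal stop codon at codon "
                                 f"{i // 3 + 1}")
            aas.append(aa)
        proteins.append("".join(aas))

    mat = np.array([list(p) for p in proteins])
    variable = changes = 0
    for j in range(mat.shape[1]):
        residues = {a for a in mat[:, j] if a != "-"}
        if len(residues) >= 2:
            variable += 1
        changes += max(len(residues) - 1, 0)
    return ProteinSummary(names=list(aln.names), proteins=proteins,
                          n_unique=len(set(proteins)),
                          variable_sites=variable, aa_changes=changes)
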