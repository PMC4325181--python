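"""FASTQ input, quality filtering, dual-MID demultiplexing and primer trimming.

A read is kept only if its Phred quality exceeds 20 at more than 95 % of bases
(both comparisons strict), then assigned to an amplicon iff its 10-bp forward
MID matches exactly, the forward primer matches with IUPAC expansion, and the
reverse-complemented reverse primer + MID match at the 3' end. Assigned reads
are trimmed to the template-only sequence. MID matching is exact by design:
the tag set was chosen with >= 3 differences between tags, and the original
workflow demanded complete MIDs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .synthetic_reads import DEFAULT_MIDS, MidAssignment, revcomp

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class Read:
    """A sequencing read with per-base Phred scores."""

    id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self):
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"{self.id}: sequence/quality length mismatch")


@dataclass
class AmpliconRecord:
    """All template-trimmed reads assigned to one (pool, fwd MID, rev MID)."""

    amplicon_id: tuple[int, str, str]
    sample_id: str
    replicate: int
    reads: list[str] = field(default_factory=list)
    n_raw: int = 0

    @property
    def n_assigned(self) -> int:
        return len(self.reads)


def read_fastq(path) -> list[Read]:
    """Parse a Sanger (Phred+33) FASTQ file."""
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(Read(id=rec.id, sequence=str(rec.seq),
                        qualities=tuple(rec.letter_annotations["phred_quality"])))
    return out


def quality_filter(read: Read, min_phred: int = 20,
                   min_fraction: float = 0.95) -> bool:
    """Pass iff (bases with Phred > min_phred) / length > min_fraction.

    Both inequalities strict, per the published rule ("> 20 at more than
    95 % bases"); relax by lowering the thresholds if needed. Empty reads fail.
    """
    n = len(read.sequence)
    if n == 0:
        return False
    good = sum(1 for q in read.qualities if q > min_phred)
    return good / n > min_fraction


def iupac_match(pattern: str, seq: str) -> bool:
    """Exact-offset match of an IUPAC-degenerate pattern against a sequence."""
    if len(pattern) != len(seq):
        return False
    return all(b in IUPAC.get(p, "") for p, b in zip(pattern, seq))


def read_mid_map(path) -> list[MidAssignment]:
    import csv

    out = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(MidAssignment(pool=int(row["pool"]),
                                     sample_id=row["sample_id"],
                                     replicate=int(row["replicate"]),
                                     fwd_mid=row["fwd_MID"],
                                     rev_mid=row["rev_MID"]))
    return out


@dataclass
class DemuxResult:
    amplicons: list[AmpliconRecord]
    n_raw: int
    n_filtered: int  # failed the quality filter
    n_unassigned: int  # passed filter but no MID/primer match

    @property
    def n_assigned(self) -> int:
        return sum(a.n_assigned for a in self.amplicons)


def demultiplex(reads: list[Read], mid_map: list[MidAssignment],
                fwd_primer: str, rev_primer: str, pool: int,
                mids: dict[str, str] | None = None, key: str = "",
                min_phred: int = 20, min_fraction: float = 0.95,
                apply_filter: bool = True) -> DemuxResult:
    """Assign quality-passing reads of one pool to amplicons by dual MIDs.

    Unknown MID combinations are counted unassigned, never an error. The
    optional ``key`` is a fixed prefix (the 454 key, e.g. TCAG) expected before
    the forward MID.
    """
    mids = mids or DEFAULT_MIDS
    entries = [m for m in mid_map if m.pool == pool]
    lookup: dict[tuple[str, str], MidAssignment] = {}
    for m in entries:
        k = (mids[m.fwd_mid], mids[m.rev_mid])
        if k in lookup:
            raise ValueError(f"duplicate MID pair {k} in pool {pool}")
        lookup[k] = m

    records = {(pool, m.fwd_mid, m.rev_mid):
               AmpliconRecord(amplicon_id=(pool, m.fwd_mid, m.rev_mid),
                              sample_id=m.sample_id, replicate=m.replicate)
               for m in entries}
    mid_len = 10
    rc_rev_primer = revcomp(rev_primer)
    n_filtered = n_unassigned = 0
    klen = len(key)

    for read in reads:
        if apply_filter and not quality_filter(read, min_phred, min_fraction):
            n_filtered += 1
            continue
        seq = read.sequence
        if klen:
            if not seq.startswith(key):
                n_unassigned += 1
                continue
            seq = seq[klen:]
        head_mid = seq[:mid_len]
        tail_mid = revcomp(seq[-mid_len:]) if len(seq) >= mid_len else ""
        hit = lookup.get((head_mid, tail_mid))
        if hit is None:
            n_unassigned += 1
            continue
        body = seq[mid_len:len(seq) - mid_len]
        f_len, r_len = len(fwd_primer), len(rev_primer)
        if len(body) < f_len + r_len + 1 \
                or not iupac_match(fwd_primer, body[:f_len]) \
                or not iupac_match(rc_rev_primer, body[len(body) - r_len:]):
            n_unassigned += 1
            continue
        rec = records[(pool, hit.fwd_mid, hit.rev_mid)]
        rec.reads.append(body[f_len:len(body) - r_len])

    for rec in records.values():
        rec.n_raw = len(reads)
    return DemuxResult(amplicons=list(records.values()), n_raw=len(reads),
                       n_filtered=n_filtered, n_unassigned=n_unassigned)


def intra_amplicon_frequency(cluster_count: int,
                             amplicon: AmpliconRecord) -> float:
    """Proportion of the amplicon's assigned reads in one cluster."""
    if amplicon.n_assigned == 0:
        raise ValueError("amplicon has no assigned reads")
    return cluster_count / amplicon.n_assigned
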