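"""Replicate-validated allele calling for multigene amplicon data.

Implements the three-step artefact classification used for multilocus MHC
genotyping:

  step 1 (per amplicon)   reads are grouped into clusters of identical
      sequences; the most frequent cluster is a putative allele; single-read
      clusters are discarded; remaining clusters are labelled ``chimera``
      (expressible as prefix-of-one + suffix-of-another more frequent
      cluster), ``diff_1_2bp`` (edit distance 1-2 to a more frequent cluster)
      or ``diff_gt2bp``.
  step 2 (per sample)     chimera / 1-2 bp clusters absent from the sample's
      replicate amplicon are putative artefacts, as are clusters chimeric in
      both replicates, and >2 bp clusters unique to a single amplicon
      dataset-wide.
  step 3 (per dataset)    retained clusters seen in both replicates become
      putative alleles if their intra-amplicon frequency exceeds every
      putative-artefact frequency in the same amplicon (required in both
      replicates); otherwise they stay unclassified. Retained clusters seen in
      one replicate only are resolved against putative alleles of other
      samples.

Post-processing then differs by dataset size: the large-sample rules drop
single-individual alleles, promote catalog-matching unclassified variants and
artefacts, and flag pervasive low-frequency variants as low-efficiency
alleles; the small-sample rules keep single-sample alleles confirmed across
replicates and promote unclassified variants shared by two or more birds.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import edlib
import numpy as np

# step-1 labels
PUTATIVE_ALLELE = "putative_allele"
CHIMERA = "chimera"
DIFF_1_2BP = "diff_1_2bp"
DIFF_GT2BP = "diff_gt2bp"
SINGLETON = "singleton_discard"

# states after steps 2-3 / post-processing
ALLELE = "allele"
ARTEFACT = "artefact"
UNCLASSIFIED = "unclassified"
DISCARDED = "discarded"


@dataclass
class Cluster:
    """A group of identical reads within one amplicon."""

    sequence: str
    count: int
    frequency: float
    label: str | None = None
    state: str = UNCLASSIFIED


@dataclass
class AmpliconClusters:
    """Step-1 view of one amplicon."""

    amplicon_id: str
    sample_id: str
    replicate: int
    n_assigned: int
    clusters: list[Cluster]

    def __post_init__(self):
        self.by_seq = {c.sequence: c for c in self.clusters}

    def surviving(self) -> list[Cluster]:
        return [c for c in self.clusters if c.label != SINGLETON]

    def max_artefact_frequency(self) -> float:
        freqs = [c.frequency for c in self.clusters if c.state == ARTEFACT]
        return max(freqs, default=0.0)


@dataclass
class SamplePair:
    sample_id: str
    r1: AmpliconClusters | None
    r2: AmpliconClusters | None

    @property
    def complete(self) -> bool:
        return self.r1 is not None and self.r2 is not None

    def amplicons(self) -> list[AmpliconClusters]:
        return [a for a in (self.r1, self.r2) if a is not None]


@dataclass
class GenotypeCall:
    sample_id: str
    alleles: frozenset[str]  # final allele sequences
    repeatability: float | None
    excluded: bool = False
    exclusion_reason: str | None = None
    low_efficiency_flags: frozenset[str] = frozenset()
    replicate_calls: tuple[frozenset[str], frozenset[str]] = (frozenset(),
                                                              frozenset())


# ---------------------------------------------------------------------------
# step 1


def cluster_reads(reads: list[str], amplicon_id: str = "", sample_id: str = "",
                  replicate: int = 1) -> AmpliconClusters:
    """Group identical reads; sort by count descending, ties lexicographic."""
    if not reads:
        raise ValueError("amplicon has no assigned reads")
    counts = Counter(reads)
    n = len(reads)
    clusters = [Cluster(sequence=s, count=c, frequency=c / n)
                for s, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))]
    return AmpliconClusters(amplicon_id=amplicon_id, sample_id=sample_id,
                            replicate=replicate, n_assigned=n,
                            clusters=clusters)


def detect_chimera(query: str, more_frequent: list[str]
                   ) -> list[tuple[str, str, int]]:
    """All (parentA, parentB, k) with parentA != parentB such that
    query = parentA[:k] + (suffix of parentB of length len(query) - k),
    1 <= k < len(query). Non-empty iff the query is chimeric."""
    out = []
    L = len(query)
    for a in more_frequent:
        for b in more_frequent:
            if a == b:
                continue
            for k in range(1, L):
                if L - k > len(b) or k > len(a):
                    continue
                if query[:k] == a[:k] and query[k:] == b[len(b) - (L - k):]:
                    out.append((a, b, k))
    return out


def _lcp_lcs_matrices(seqs: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise longest-common-prefix and -suffix lengths (vectorised).

    Rows are padded with row-distinct sentinels so matches never extend past
    either sequence's end.
    """
    n = len(seqs)
    lmax = max(len(s) for s in seqs)
    fwd = np.zeros((n, lmax), dtype=np.int16)
    rev = np.zeros((n, lmax), dtype=np.int16)
    for i, s in enumerate(seqs):
        arr = np.frombuffer(s.encode(), dtype=np.uint8).astype(np.int16)
        fwd[i, :len(s)] = arr
        fwd[i, len(s):] = 256 + i
        rev[i, :len(s)] = arr[::-1]
        rev[i, len(s):] = 256 + i
    eq_f = fwd[:, None, :] == fwd[None, :, :]
    eq_r = rev[:, None, :] == rev[None, :, :]
    lcp = eq_f.cumprod(axis=2).sum(axis=2)
    lcs = eq_r.cumprod(axis=2).sum(axis=2)
    return lcp, lcs


def _chimera_flags(clusters: list[Cluster]) -> list[bool]:
    """For each cluster, whether it is a prefix+suffix join of two distinct
    strictly-more-frequent clusters. Equivalent to ``detect_chimera`` being
    non-empty: a valid breakpoint k exists iff some pair A != B has
    lcp(q, A) >= 1, lcs(q, B) >= 1 and lcp(q, A) + lcs(q, B) >= len(q)."""
    n = len(clusters)
    if n < 3:
        return [False] * n
    lcp, lcs = _lcp_lcs_matrices([c.sequence for c in clusters])
    counts = np.array([c.count for c in clusters])
    flags = [False] * n
    for qi in range(n):
        parents = np.flatnonzero(counts > counts[qi])
        if len(parents) < 2:
            continue
        L = len(clusters[qi].sequence)
        p_lcp = lcp[qi, parents].astype(float)
        p_lcs = lcs[qi, parents].astype(float)
        p_lcp[p_lcp < 1] = -np.inf
        p_lcs[p_lcs < 1] = -np.inf
        i1 = int(np.argmax(p_lcp))
        j1 = int(np.argmax(p_lcs))
        if i1 != j1:
            best = p_lcp[i1] + p_lcs[j1]
        else:
            a2 = np.partition(p_lcp, -2)[-2]
            b2 = np.partition(p_lcs, -2)[-2]
            best = max(p_lcp[i1] + b2, a2 + p_lcs[j1])
        if best >= L:
            flags[qi] = True
    return flags


def classify_step1(amplicon: AmpliconClusters) -> AmpliconClusters:
    """Label clusters: singleton discard, putative allele (all clusters tied
    at the maximum count), chimera, 1-2 bp or >2 bp difference."""
    clusters = amplicon.clusters
    max_count = clusters[0].count
    survivors = [c for c in clusters if c.count > 1]
    flags = _chimera_flags(survivors)
    flag_of = {c.sequence: f for c, f in zip(survivors, flags)}

    for c in clusters:
        if c.count == 1:
            c.label = SINGLETON
            c.state = DISCARDED
        elif c.count == max_count:
            c.label = PUTATIVE_ALLELE
            c.state = ALLELE
        elif flag_of[c.sequence]:
            c.label = CHIMERA
        else:
            close = False
            for p in survivors:
                if p.count <= c.count:
                    continue
                d = edlib.align(c.sequence, p.sequence, task="distance",
                                k=2)["editDistance"]
                if d != -1:
                    close = True
                    break
            c.label = DIFF_1_2BP if close else DIFF_GT2BP
    return amplicon


# ---------------------------------------------------------------------------
# steps 2-3 (dataset level)


def build_dataset_index(pairs: list[SamplePair]) -> dict[str, set[str]]:
    """sequence -> amplicon ids containing it as a non-singleton cluster."""
    index: dict[str, set[str]] = defaultdict(set)
    for pair in pairs:
        for amp in pair.amplicons():
            for c in amp.surviving():
                index[c.sequence].add(amp.amplicon_id)
    return dict(index)


def classify_step2(pair: SamplePair, dataset_index: dict[str, set[str]]
                   ) -> None:
    """Mark putative artefacts by replicate comparison (in place)."""
    if not pair.complete:
        return
    for amp, other in ((pair.r1, pair.r2), (pair.r2, pair.r1)):
        other_seqs = {c.sequence for c in other.surviving()}
        for c in amp.surviving():
            if c.label in (CHIMERA, DIFF_1_2BP) and c.sequence not in other_seqs:
                c.state = ARTEFACT
            elif c.label == CHIMERA \
                    and other.by_seq.get(c.sequence) is not None \
                    and other.by_seq[c.sequence].label == CHIMERA:
                c.state = ARTEFACT
            elif c.label == DIFF_GT2BP \
                    and len(dataset_index.get(c.sequence, set())) == 1:
                c.state = ARTEFACT


def classify_step3(pairs: list[SamplePair]) -> None:
    """Resolve retained clusters into putative alleles / unclassified (in
    place), comparing frequencies against each amplicon's artefact list.

    A both-replicate cluster is promoted only if its frequency beats the
    amplicon-local maximum artefact frequency in both replicates (an empty
    artefact list passes vacuously). One-replicate clusters are resolved
    against the provisional putative-allele sets of other samples.
    """
    # phase A: within-sample frequency comparison for both-replicate clusters
    for pair in pairs:
        if not pair.complete:
            continue
        bar1 = pair.r1.max_artefact_frequency()
        bar2 = pair.r2.max_artefact_frequency()
        for c1 in pair.r1.surviving():
            c2 = pair.r2.by_seq.get(c1.sequence)
            if c2 is None or c2.label == SINGLETON \
                    or ARTEFACT in (c1.state, c2.state):
                continue
            if c1.frequency > bar1 and c2.frequency > bar2:
                for c in (c1, c2):
                    if c.label in (DIFF_1_2BP, DIFF_GT2BP) \
                            and c.state == UNCLASSIFIED:
                        c.state = ALLELE

    # provisional putative alleles per sample (sequence -> samples)
    allele_samples: dict[str, set[str]] = defaultdict(set)
    for pair in pairs:
        for amp in pair.amplicons():
            for c in amp.clusters:
                if c.state == ALLELE:
                    allele_samples[c.sequence].add(pair.sample_id)

    # phase B: one-replicate >2 bp clusters and retained chimeras
    for pair in pairs:
        for amp in pair.amplicons():
            other = pair.r2 if amp is pair.r1 else pair.r1
            for c in amp.surviving():
                if c.state != UNCLASSIFIED:
                    continue
                elsewhere = allele_samples.get(c.sequence, set()) \
                    - {pair.sample_id}
                if c.label == DIFF_GT2BP:
                    in_both = other is not None \
                        and c.sequence in other.by_seq \
                        and other.by_seq[c.sequence].label != SINGLETON
                    if not in_both:
                        c.state = UNCLASSIFIED if elsewhere else ARTEFACT
                elif c.label == CHIMERA:
                    if elsewhere:
                        c.state = ALLELE
                    # else stays unclassified


# ---------------------------------------------------------------------------
# post-processing


@dataclass
class PipelineResult:
    catalog: dict[str, str]  # allele name -> sequence
    calls: dict[str, GenotypeCall]
    low_efficiency: frozenset[str]  # flagged catalog sequences
    report: dict[str, int]
    pairs: list[SamplePair] = field(default_factory=list, repr=False)

    @property
    def mean_repeatability(self) -> float:
        vals = [c.repeatability for c in self.calls.values()
                if c.repeatability is not None and not c.excluded]
        return float(np.mean(vals)) if vals else float("nan")

    def catalog_name(self, sequence: str) -> str | None:
        for name, seq in self.catalog.items():
            if seq == sequence:
                return name
        return None


def _allele_samples(pairs: list[SamplePair]) -> dict[str, set[str]]:
    out: dict[str, set[str]] = defaultdict(set)
    for pair in pairs:
        for amp in pair.amplicons():
            for c in amp.clusters:
                if c.state == ALLELE:
                    out[c.sequence].add(pair.sample_id)
    return out


def _collect_calls(pairs: list[SamplePair], catalog_seqs: set[str],
                   flagged: set[str], allele_prefix: str,
                   excluded: dict[str, str] | None = None
                   ) -> tuple[dict[str, str], dict[str, GenotypeCall]]:
    """Final per-sample calls (union of replicates) and named catalog."""
    excluded = excluded or {}
    calls: dict[str, GenotypeCall] = {}
    seq_samples: Counter = Counter()
    for pair in pairs:
        rep_calls = []
        for amp in pair.amplicons():
            rep_calls.append(frozenset(
                c.sequence for c in amp.clusters
                if c.state == ALLELE and c.sequence in catalog_seqs))
        while len(rep_calls) < 2:
            rep_calls.append(frozenset())
        union = rep_calls[0] | rep_calls[1]
        for s in union:
            seq_samples[s] += 1
        if pair.sample_id in excluded:
            calls[pair.sample_id] = GenotypeCall(
                sample_id=pair.sample_id, alleles=frozenset(),
                repeatability=None, excluded=True,
                exclusion_reason=excluded[pair.sample_id])
            continue
        rep = None
        if pair.complete and (rep_calls[0] or rep_calls[1]):
            rep = repeatability(rep_calls[0], rep_calls[1])
        calls[pair.sample_id] = GenotypeCall(
            sample_id=pair.sample_id, alleles=union, repeatability=rep,
            low_efficiency_flags=frozenset(union & flagged),
            replicate_calls=(rep_calls[0], rep_calls[1]))

    ordered = sorted(catalog_seqs, key=lambda s: (-seq_samples[s], s))
    catalog = {f"{allele_prefix}{i + 1:02d}": s for i, s in enumerate(ordered)}
    return catalog, calls


def postprocess_large(pairs: list[SamplePair], min_individuals: int = 2,
                      prevalence_threshold: float = 0.8,
                      allele_prefix: str = "ALL",
                      excluded: dict[str, str] | None = None
                      ) -> PipelineResult:
    """Large-sample post-processing.

    (a) putative alleles seen in fewer than ``min_individuals`` individuals
    are discarded; (b) unclassified variants matching a surviving catalog
    allele are promoted where they occur; (d) artefacts matching a catalog
    allele, present in both of a sample's amplicons at a frequency above the
    amplicon's least frequent called catalog entry, are promoted; (c, last)
    unclassified variants present in both amplicons of more than
    ``prevalence_threshold`` of individuals are flagged low-efficiency
    alleles. Promotions never resurrect alleles dropped by (a); the
    low-efficiency flag may rescue them, as it acts on the unclassified list.
    """
    allele_samples = _allele_samples(pairs)
    catalog_seqs = {s for s, ids in allele_samples.items()
                    if len(ids) >= min_individuals}

    # (a) discard single-individual putative alleles
    for pair in pairs:
        for amp in pair.amplicons():
            for c in amp.clusters:
                if c.state == ALLELE and c.sequence not in catalog_seqs:
                    c.state = DISCARDED

    # (b) promote catalog-matching unclassified variants
    for pair in pairs:
        for amp in pair.amplicons():
            for c in amp.clusters:
                if c.state == UNCLASSIFIED and c.sequence in catalog_seqs:
                    c.state = ALLELE

    # (d) promote catalog-matching artefacts confirmed across replicates
    for pair in pairs:
        if not pair.complete:
            continue
        for amp, other in ((pair.r1, pair.r2), (pair.r2, pair.r1)):
            called = [c.frequency for c in amp.clusters
                      if c.state == ALLELE and c.sequence in catalog_seqs]
            if not called:
                continue
            floor = min(called)
            for c in amp.clusters:
                if c.state != ARTEFACT or c.sequence not in catalog_seqs:
                    continue
                o = other.by_seq.get(c.sequence)
                if o is not None and o.label != SINGLETON \
                        and c.frequency > floor:
                    c.state = ALLELE

    # (c) flag pervasive low-frequency unclassified variants
    n_complete = sum(1 for p in pairs if p.complete) or 1
    both_amp_counts: Counter = Counter()
    for pair in pairs:
        if not pair.complete:
            continue
        u1 = {c.sequence for c in pair.r1.clusters if c.state == UNCLASSIFIED}
        u2 = {c.sequence for c in pair.r2.clusters if c.state == UNCLASSIFIED}
        for s in u1 & u2:
            both_amp_counts[s] += 1
    flagged = {s for s, n in both_amp_counts.items()
               if s not in catalog_seqs and n / n_complete > prevalence_threshold}
    for pair in pairs:
        if not pair.complete:
            continue
        for s in flagged:
            c1, c2 = pair.r1.by_seq.get(s), pair.r2.by_seq.get(s)
            if c1 is not None and c2 is not None \
                    and c1.state == UNCLASSIFIED and c2.state == UNCLASSIFIED:
                c1.state = ALLELE
                c2.state = ALLELE
    catalog_seqs |= flagged

    catalog, calls = _collect_calls(pairs, catalog_seqs, flagged,
                                    allele_prefix, excluded)
    return PipelineResult(catalog=catalog, calls=calls,
                          low_efficiency=frozenset(flagged),
                          report=_report(pairs), pairs=pairs)


def postprocess_small(pairs: list[SamplePair], allele_prefix: str = "ALL",
                      excluded: dict[str, str] | None = None
                      ) -> PipelineResult:
    """Small-sample post-processing (no single-individual drop).

    An allele confirmed in both replicates of even a single sample is kept; an
    allele seen in one amplicon that occurs elsewhere as an unclassified
    variant is kept; unclassified variants present in both replicates of at
    least two birds are promoted to alleles.
    """
    allele_samples = _allele_samples(pairs)

    uncl_samples: dict[str, set[str]] = defaultdict(set)
    uncl_both: Counter = Counter()
    for pair in pairs:
        amp_seqs = []
        for amp in pair.amplicons():
            seqs = {c.sequence for c in amp.clusters
                    if c.state == UNCLASSIFIED}
            amp_seqs.append(seqs)
            for s in seqs:
                uncl_samples[s].add(pair.sample_id)
        if len(amp_seqs) == 2:
            for s in amp_seqs[0] & amp_seqs[1]:
                uncl_both[s] += 1

    catalog_seqs: set[str] = set()
    for seq, samples in allele_samples.items():
        if len(samples) >= 2:
            catalog_seqs.add(seq)
            continue
        (sid,) = samples
        pair = next(p for p in pairs if p.sample_id == sid)
        in_both = pair.complete and all(
            (c := amp.by_seq.get(seq)) is not None and c.state == ALLELE
            for amp in pair.amplicons())
        if in_both:
            catalog_seqs.add(seq)  # allele in both replicates of one sample
        elif uncl_samples.get(seq, set()) - {sid}:
            catalog_seqs.add(seq)  # allele once + unclassified elsewhere

    # unclassified variants in both replicates of >= 2 birds become alleles
    promoted = {s for s, n in uncl_both.items()
                if n >= 2 and s not in catalog_seqs}
    catalog_seqs |= promoted

    for pair in pairs:
        for amp in pair.amplicons():
            for c in amp.clusters:
                if c.state == UNCLASSIFIED and c.sequence in catalog_seqs:
                    c.state = ALLELE
                elif c.state == ALLELE and c.sequence not in catalog_seqs:
                    c.state = DISCARDED

    catalog, calls = _collect_calls(pairs, catalog_seqs, set(),
                                    allele_prefix, excluded)
    return PipelineResult(catalog=catalog, calls=calls,
                          low_efficiency=frozenset(),
                          report=_report(pairs), pairs=pairs)


def repeatability(call_r1: frozenset | set, call_r2: frozenset | set) -> float:
    """Percent shared alleles between replicate calls: 100 * |A & B| / |A | B|."""
    union = set(call_r1) | set(call_r2)
    if not union:
        raise ValueError("repeatability undefined for two empty calls")
    return 100.0 * len(set(call_r1) & set(call_r2)) / len(union)


def _report(pairs: list[SamplePair]) -> dict[str, int]:
    label_counts: Counter = Counter()
    state_counts: Counter = Counter()
    for pair in pairs:
        for amp in pair.amplicons():
            for c in amp.clusters:
                label_counts[c.label] += 1
                state_counts[c.state] += 1
    out = {f"label_{k}": v for k, v in sorted(label_counts.items(),
                                              key=lambda kv: str(kv[0]))}
    out.update({f"state_{k}": v for k, v in sorted(state_counts.items())})
    out["n_amplicons"] = sum(len(p.amplicons()) for p in pairs)
    out["n_samples"] = len(pairs)
    return out


# ---------------------------------------------------------------------------
# pipeline driver


def build_pairs(amplicons) -> list[SamplePair]:
    """Cluster + step-1 classify amplicon read sets and pair replicates.

    ``amplicons`` is any iterable of objects with ``sample_id``, ``replicate``
    and ``reads`` attributes (simulated amplicons or demultiplexed records).
    """
    by_sample: dict[str, dict[int, AmpliconClusters]] = defaultdict(dict)
    for amp in amplicons:
        if not amp.reads:
            continue
        amp_id = str(getattr(amp, "amplicon_id", None)
                     or f"{amp.sample_id}_r{amp.replicate}")
        ac = cluster_reads(amp.reads, amplicon_id=amp_id,
                           sample_id=amp.sample_id, replicate=amp.replicate)
        classify_step1(ac)
        by_sample[amp.sample_id][amp.replicate] = ac
    return [SamplePair(sample_id=sid, r1=reps.get(1), r2=reps.get(2))
            for sid, reps in sorted(by_sample.items())]


def run_pipeline(amplicons, mode: str = "large", min_individuals: int = 2,
                 prevalence_threshold: float = 0.8,
                 allele_prefix: str = "ALL",
                 min_reads: int | None = None) -> PipelineResult:
    """Full genotyping: step 1-3 classification plus post-processing.

    ``min_reads`` applies a per-replicate minimum read-depth threshold (e.g. a
    T1 result): samples with any replicate below it are excluded from the
    final calls, with the reason recorded, but their amplicons still inform
    the dataset-wide classification.
    """
    pairs = build_pairs(amplicons)
    index = build_dataset_index(pairs)
    for pair in pairs:
        classify_step2(pair, index)
    classify_step3(pairs)

    excluded: dict[str, str] = {}
    if min_reads is not None:
        for pair in pairs:
            low = [a for a in pair.amplicons() if a.n_assigned < min_reads]
            if low:
                excluded[pair.sample_id] = (
                    f"replicate below minimum read depth {min_reads} "
                    f"({', '.join(f'{a.amplicon_id}={a.n_assigned}' for a in low)})")
    for pair in pairs:
        if not pair.complete:
            excluded.setdefault(pair.sample_id, "missing replicate amplicon")

    if mode == "large":
        return postprocess_large(pairs, min_individuals, prevalence_threshold,
                                 allele_prefix, excluded)
    if mode == "small":
        return postprocess_small(pairs, allele_prefix, excluded)
    raise ValueError(f"unknown mode {mode!r}")
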