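"""Relative allele amplification efficiency and minimum read-depth thresholds.

Alleles of a multigene family amplify unevenly under shared degenerate
primers. Assuming an allele's amplification efficiency is independent of the
genotype it sits in, within-amplicon read-count ratios satisfy
``E[n_i / n_j] ~ e_i / e_j``, so log-ratios over all within-amplicon allele
pairs form a linear system in log(e). We solve it by weighted least squares
(amplicons weighted by total reads) and anchor the scale at a reference
allele (e_ref = 1) -- the reference is arbitrary because only ratios are
identified.

The worst-case minimum read depth (a conservative variant of Galan's T1) asks:
for a genotype of k alleles whose rarest allele has relative efficiency e_min
against k-1 average amplifiers, how many reads N guarantee seeing that allele
at least m times with the stated coverage probability? The worst-case allele
frequency is p_min = e_min / (e_min + (k - 1)) and N is the smallest integer
with P(Binomial(N, p_min) >= m) >= coverage, applied to each replicate
independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class EfficiencyTable:
    """Estimated relative efficiencies, anchored at a reference allele."""

    efficiencies: dict[str, float]  # allele -> e_hat (NaN if disconnected)
    reference: str
    support: dict[str, int]  # amplicons informing each allele

    def __getitem__(self, allele: str) -> float:
        return self.efficiencies[allele]

    @property
    def e_min(self) -> float:
        vals = [e for e in self.efficiencies.values() if np.isfinite(e)]
        return min(vals)

    def summary(self) -> pd.DataFrame:
        rows = [{"allele": a, "efficiency": e,
                 "support": self.support.get(a, 0),
                 "is_reference": a == self.reference}
                for a, e in sorted(self.efficiencies.items(),
                                   key=lambda kv: -kv[1])]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class T1Result:
    k_alleles: int
    e_min: float
    m_min: int
    coverage: float
    n_min: int  # minimum reads per amplicon


def estimate_efficiencies(amplicon_counts: list[dict[str, int]],
                          reference: str) -> EfficiencyTable:
    """Weighted log-ratio least squares over within-amplicon allele pairs.

    ``amplicon_counts`` maps allele -> read count per amplicon (called alleles
    only). Pairs require both counts >= 1 (no pseudo-counts). Alleles not
    connected to the reference through shared amplicons are reported as NaN.
    """
    alleles = sorted({a for amp in amplicon_counts for a in amp})
    if reference not in alleles:
        raise ValueError(f"reference {reference!r} absent from all amplicons")
    idx = {a: i for i, a in enumerate(alleles)}
    m = len(alleles)

    # connectivity to the reference via shared amplicons
    adj: dict[str, set[str]] = {a: set() for a in alleles}
    support: dict[str, int] = {a: 0 for a in alleles}
    for amp in amplicon_counts:
        present = [a for a, n in amp.items() if n >= 1]
        for a in present:
            support[a] += 1
        for a in present:
            adj[a].update(p for p in present if p != a)
    reachable = {reference}
    frontier = [reference]
    while frontier:
        nxt = []
        for a in frontier:
            for b in adj[a]:
                if b not in reachable:
                    reachable.add(b)
                    nxt.append(b)
        frontier = nxt

    # normal equations for sum_pairs w * (x_i - x_j - y_ij)^2
    ata = np.zeros((m, m))
    atb = np.zeros(m)
    for amp in amplicon_counts:
        present = sorted((a for a, n in amp.items() if n >= 1), key=idx.get)
        w = float(sum(amp[a] for a in present))
        for ii, a in enumerate(present):
            for b in present[ii + 1:]:
                y = np.log(amp[a] / amp[b])
                i, j = idx[a], idx[b]
                ata[i, i] += w
                ata[j, j] += w
                ata[i, j] -= w
                ata[j, i] -= w
                atb[i] += w * y
                atb[j] -= w * y

    keep = [idx[a] for a in alleles if a in reachable and a != reference]
    x = np.full(m, np.nan)
    x[idx[reference]] = 0.0
    if keep:
        sub = np.ix_(keep, keep)
        sol = np.linalg.lstsq(ata[sub], atb[keep], rcond=None)[0]
        for pos, i in enumerate(keep):
            x[i] = sol[pos]

    eff = {a: float(np.exp(x[idx[a]])) if a in reachable else float("nan")
           for a in alleles}
    return EfficiencyTable(efficiencies=eff, reference=reference,
                           support=support)


def t1_threshold(k_alleles: int, e_min: float, m_min: int = 2,
                 coverage: float = 0.999) -> T1Result:
    """Smallest N with P(Binomial(N, p_min) >= m_min) >= coverage, where
    p_min = e_min / (e_min + (k_alleles - 1))."""
    if k_alleles < 1:
        raise ValueError("k_alleles must be >= 1")
    if e_min <= 0:
        raise ValueError("e_min must be > 0")
    if m_min < 1:
        raise ValueError("m_min must be >= 1")
    if not 0.0 < coverage < 1.0:
        raise ValueError("coverage must be in (0, 1)")
    p_min = e_min / (e_min + (k_alleles - 1))

    def ok(n: int) -> bool:
        return stats.binom.sf(m_min - 1, n, p_min) >= coverage

    lo = m_min
    hi = m_min
    while not ok(hi):
        hi *= 2
    while lo < hi:
        mid = (lo + hi) // 2
        if ok(mid):
            hi = mid
        else:
            lo = mid + 1
    return T1Result(k_alleles=k_alleles, e_min=e_min, m_min=m_min,
                    coverage=coverage, n_min=lo)


def apply_t1(amplicons, t1: T1Result) -> tuple[set[str], dict[str, str]]:
    """Partition samples by the minimum read-depth rule.

    A sample is excluded iff either replicate amplicon has strictly fewer
    assigned reads than the threshold. Returns (kept sample ids, excluded
    sample id -> reason).
    """
    from collections import defaultdict

    depth: dict[str, list] = defaultdict(list)
    for amp in amplicons:
        n = getattr(amp, "n_assigned", None)
        if n is None:
            n = len(amp.reads)
        depth[amp.sample_id].append((getattr(amp, "replicate", 0), n))
    kept: set[str] = set()
    excluded: dict[str, str] = {}
    for sid, reps in depth.items():
        low = [(r, n) for r, n in reps if n < t1.n_min]
        if low:
            excluded[sid] = "; ".join(
                f"replicate {r} has {n} reads < T1 threshold {t1.n_min}"
                for r, n in low)
        else:
            kept.add(sid)
    return kept, excluded


def counts_from_pipeline(result, catalog_only: bool = True
                         ) -> list[dict[str, int]]:
    """Per-amplicon read counts of called alleles, for efficiency estimation."""
    from .genotyping import ALLELE

    out = []
    catalog_seqs = set(result.catalog.values())
    name_of = {seq: name for name, seq in result.catalog.items()}
    for pair in result.pairs:
        for amp in pair.amplicons():
            counts = {}
            for c in amp.clusters:
                if c.state != ALLELE:
                    continue
                if catalog_only and c.sequence not in catalog_seqs:
                    continue
                counts[name_of.get(c.sequence, c.sequence)] = c.count
            if len(counts) >= 2:
                out.append(counts)
    return out
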