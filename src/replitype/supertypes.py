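"""Functional supertype clustering of alleles from amino-acid z-descriptors.

Each unique protein sequence over the analysed positions (e.g. the peptide
binding region) is encoded as the concatenation of five physicochemical
z-scale descriptors per residue, and the rows are clustered by k-means over a
range of k. Model selection uses BIC = n * ln(WSS / n) + k * ln(n), averaged
over several k-means restarts per k; the chosen k minimises the mean BIC.
With distinct, well-separated rows the curve is minimised at k = n (every
allele its own supertype), the all-singleton outcome observed for strongly
diverged allele sets.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning


def load_z_scales() -> pd.DataFrame:
    """The published five z-scale descriptors for the 20 standard residues."""
    ref = importlib.resources.files("replitype.data") \
        .joinpath("zscales_sandberg1998.tsv")
    with ref.open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    return df.set_index("aa")


@dataclass
class ZDescriptorMatrix:
    """Rows: unique protein sequences over the analysed positions; columns:
    five descriptors per position."""

    matrix: np.ndarray
    row_sequences: list[str]  # unique sequences over the selected positions
    members: dict[str, list[str]]  # row sequence -> allele names collapsed
    positions: list[int]

    def __post_init__(self):
        if len(set(self.row_sequences)) != len(self.row_sequences):
            raise ValueError("duplicate rows after collapsing")
        if self.matrix.shape != (len(self.row_sequences),
                                 5 * len(self.positions)):
            raise ValueError("descriptor matrix has wrong shape")


@dataclass
class SupertypeModel:
    chosen_k: int
    bic_curve: pd.DataFrame  # columns k, mean_bic
    assignments: np.ndarray  # cluster id per row, best run at chosen k
    n_runs: int
    seed: int
    rows: list[str] = field(default_factory=list)


def z_descriptor_matrix(proteins: dict[str, str],
                        positions: list[int] | None = None,
                        strict: bool = False) -> ZDescriptorMatrix:
    """Encode proteins as z-descriptor rows over 1-based positions.

    Sequences identical over the selected positions collapse to one row. By
    default, positions where any sequence carries a gap (e.g. around a
    one-residue insertion) are dropped before encoding; with ``strict`` a gap
    raises instead.
    """
    z = load_z_scales()
    names = sorted(proteins)
    length = {len(proteins[n]) for n in names}
    if len(length) != 1:
        raise ValueError("proteins must be aligned to equal length")
    length = length.pop()
    positions = list(positions) if positions else list(range(1, length + 1))
    if any(p < 1 or p > length for p in positions):
        raise ValueError("position outside protein length")

    kept = []
    for p in positions:
        gapped = [n for n in names if proteins[n][p - 1] not in z.index]
        if gapped and strict:
            raise ValueError(
                f"residue {proteins[gapped[0]][p - 1]!r} at position {p} of "
                f"{gapped[0]} has no descriptor")
        if not gapped:
            kept.append(p)
    if not kept:
        raise ValueError("no fully occupied positions to analyse")

    members: dict[str, list[str]] = {}
    for n in names:
        key = "".join(proteins[n][p - 1] for p in kept)
        members.setdefault(key, []).append(n)
    rows = sorted(members)
    mat = np.array([np.concatenate([z.loc[aa].to_numpy() for aa in row])
                    for row in rows])
    return ZDescriptorMatrix(matrix=mat, row_sequences=rows, members=members,
                             positions=kept)


def _bic(wss: float, n: int, k: int) -> float:
    wss = max(wss, np.finfo(float).eps)  # keep BIC finite at perfect fits
    return n * np.log(wss / n) + k * np.log(n)


def kmeans_bic_scan(matrix: np.ndarray, k_max: int, n_runs: int = 4,
                    seed: int = 0) -> SupertypeModel:
    """k-means over k = 1..k_max with BIC model selection.

    Each k is fitted ``n_runs`` times from distinct derived seeds (k-means++
    initialisation); the per-k BIC is the mean over runs and the assignment
    comes from the best (lowest-WSS) run at the chosen k. Ties in mean BIC
    resolve to the smaller k.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if k_max > n:
        raise ValueError("k_max cannot exceed the number of rows")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if n == 1:
        return SupertypeModel(chosen_k=1,
                              bic_curve=pd.DataFrame({"k": [1],
                                                      "mean_bic": [np.nan]}),
                              assignments=np.zeros(1, dtype=int),
                              n_runs=n_runs, seed=seed)

    run_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1,
                                                     size=(k_max, n_runs))
    rows = []
    best_models: dict[int, np.ndarray] = {}
    for k in range(1, k_max + 1):
        bics, best_wss, best_assign = [], np.inf, None
        for r in range(n_runs):
            if k == 1:
                centre = matrix.mean(axis=0)
                wss = float(((matrix - centre) ** 2).sum())
                assign = np.zeros(n, dtype=int)
            else:
                km = KMeans(n_clusters=k, n_init=1, init="k-means++",
                            max_iter=100, tol=1e-6,
                            random_state=int(run_seeds[k - 1, r]))
                with warnings.catch_warnings():
                    # duplicate rows legitimately yield < k distinct clusters
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    assign = km.fit_predict(matrix)
                wss = float(km.inertia_)
            bics.append(_bic(wss, n, k))
            if wss < best_wss:
                best_wss, best_assign = wss, assign
        rows.append({"k": k, "mean_bic": float(np.mean(bics))})
        best_models[k] = best_assign
    curve = pd.DataFrame(rows)
    chosen = int(curve.loc[curve["mean_bic"].idxmin(), "k"])
    return SupertypeModel(chosen_k=chosen, bic_curve=curve,
                          assignments=best_models[chosen], n_runs=n_runs,
                          seed=seed)


def supertype_report(model: SupertypeModel,
                     zmat: ZDescriptorMatrix) -> pd.DataFrame:
    """Map every input allele (including collapsed duplicates) to its
    supertype id (1-based)."""
    rows = []
    for row_seq, cluster in zip(zmat.row_sequences, model.assignments):
        for allele in zmat.members[row_seq]:
            rows.append({"allele": allele, "supertype": int(cluster) + 1})
    return pd.DataFrame(sorted(rows, key=lambda r: r["allele"]))


def supertype_alleles(proteins: dict[str, str],
                      positions: list[int] | None = None,
                      k_max: int | None = None, n_runs: int = 4,
                      seed: int = 0) -> tuple[SupertypeModel, pd.DataFrame]:
    """Convenience: encode, scan and report in one call."""
    zmat = z_descriptor_matrix(proteins, positions)
    k_max = k_max if k_max is not None else len(zmat.row_sequences)
    model = kmeans_bic_scan(zmat.matrix, k_max=k_max, n_runs=n_runs, seed=seed)
    model.rows = zmat.row_sequences
    return model, supertype_report(model, zmat)
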