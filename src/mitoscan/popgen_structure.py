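"""Between-group differentiation: haplogroup-frequency FST, AMOVA PhiST,
pairwise mismatch distances, and a neighbor-joining QC tree.

Wright's FST over haplogroup frequencies treats haplogroups as alleles and
uses the GST-style form ``(H_T - H_S) / H_T`` on pooled vs within-group
gene diversities.  PhiST is the two-level AMOVA fixation index on squared
pairwise sequence distances.  Both carry a label-permutation p-value
``(b + 1) / (m + 1)`` with a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_and_matrix import MitoSequence, AlignmentError, VALID_BASES

logger = logging.getLogger("mitoscan")


class UndefinedFstError(ValueError):
    """Total diversity is zero (a single haplogroup): FST undefined."""


class AmovaError(ValueError):
    """Group structure too small for the AMOVA decomposition."""


@dataclass
class FstResult:
    estimate: float
    p_value: float
    n_permutations: int
    seed: int | None
    flavor: str  # "haplogroup_frequency" | "phi_st_pairwise"


@dataclass
class DistanceMatrix:
    """Pairwise mismatch counts; symmetric with zero diagonal."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T) or np.any(np.diag(self.d) != 0):
            raise ValueError("matrix must be symmetric with zero diagonal")


# ---------------------------------------------------------------------------
# haplogroup-frequency FST
# ---------------------------------------------------------------------------


def _gst(freq_by_group: np.ndarray, n_by_group: np.ndarray) -> float:
    """(H_T - H_S)/H_T from a (groups x haplogroups) frequency matrix."""
    w = n_by_group / n_by_group.sum()
    pooled = w @ freq_by_group
    h_t = 1.0 - np.sum(pooled**2)
    h_s = float(np.sum(w * (1.0 - np.sum(freq_by_group**2, axis=1))))
    if h_t == 0.0:
        raise UndefinedFstError("H_T is zero: only one haplogroup present")
    return (h_t - h_s) / h_t


def haplogroup_fst(
    counts: Mapping[str, Mapping[str, int]],
    n_permutations: int = 10_000,
    seed: int | None = 0,
) -> FstResult:
    """Wright's FST over haplogroup frequency distributions.

    ``counts`` maps group -> haplogroup -> sample count.  The permutation
    null shuffles sample group labels and recomputes the estimate;
    ``p = (#permuted >= observed + 1) / (m + 1)``.
    """
    groups = sorted(counts)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    hgs = sorted({h for g in groups for h in counts[g] if counts[g][h] > 0})
    if len(hgs) < 2:
        raise UndefinedFstError("need >= 2 haplogroups with nonzero count")
    mat = np.array([[counts[g].get(h, 0) for h in hgs] for g in groups], dtype=float)
    n_g = mat.sum(axis=1)
    if np.any(n_g == 0):
        raise ValueError("every group needs >= 1 sample")
    observed = _gst(mat / n_g[:, None], n_g)

    # flat sample-level representation for label shuffling
    labels = np.repeat(
        np.arange(len(groups)), n_g.astype(int)
    )
    hap_idx = np.concatenate(
        [np.repeat(np.arange(len(hgs)), mat[i].astype(int)) for i in range(len(groups))]
    )
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        pm = np.zeros_like(mat)
        np.add.at(pm, (perm, hap_idx), 1.0)
        if _gst(pm / pm.sum(axis=1)[:, None], pm.sum(axis=1)) >= observed:
            b += 1
    p = (b + 1) / (n_permutations + 1)
    return FstResult(
        estimate=float(observed),
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed,
        flavor="haplogroup_frequency",
    )


# ---------------------------------------------------------------------------
# pairwise distances and PhiST
# ---------------------------------------------------------------------------


def pairwise_differences(seqs: Sequence[MitoSequence]) -> DistanceMatrix:
    """Count per-pair mismatches over unambiguous positions.

    A position contributes to pair (i, j) only when both bases are in
    {A, C, G, T} (pairwise deletion of N/IUPAC/gap columns).
    """
    if not seqs:
        raise ValueError("no sequences")
    L = len(seqs[0].bases)
    for s in seqs:
        if len(s.bases) != L:
            raise AlignmentError(f"sample {s.sample_id!r} length differs")
    mat = np.frombuffer(
        "".join(s.bases for s in seqs).encode("ascii"), dtype=np.uint8
    ).reshape(len(seqs), L)
    valid = np.isin(mat, np.frombuffer(b"ACGT", dtype=np.uint8))
    n = len(seqs)
    d = np.zeros((n, n))
    usable = np.zeros((n, n), dtype=int)
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        diff = (mat[i] != mat[i + 1 :]) & both
        d[i, i + 1 :] = diff.sum(axis=1)
        usable[i, i + 1 :] = both.sum(axis=1)
    d += d.T
    logger.info(
        "pairwise distances: %d samples, min usable sites per pair %d",
        n, int(usable[np.triu_indices(n, 1)].min()) if n > 1 else 0,
    )
    return DistanceMatrix(ids=[s.sample_id for s in seqs], d=d)


def _phi_from_d2(
    d2: np.ndarray, group_idx: list[np.ndarray], n: int
) -> float:
    """PhiST from squared distances and per-group index arrays."""
    ssd_total = d2.sum() / (2.0 * n)
    ssd_within = 0.0
    for idx in group_idx:
        sub = d2[np.ix_(idx, idx)]
        ssd_within += sub.sum() / (2.0 * len(idx))
    ssd_among = ssd_total - ssd_within
    g = len(group_idx)
    df_among = g - 1
    df_within = n - g
    ms_among = ssd_among / df_among
    sigma_w = ssd_within / df_within
    sizes = np.array([len(idx) for idx in group_idx], dtype=float)
    n_c = (n - np.sum(sizes**2) / n) / df_among
    sigma_a = (ms_among - sigma_w) / n_c
    denom = sigma_a + sigma_w
    if denom == 0.0:
        return 0.0
    return sigma_a / denom


def phi_st(
    dm: DistanceMatrix,
    groups: Mapping[str, str],
    n_permutations: int = 10_000,
    seed: int | None = 0,
) -> FstResult:
    """AMOVA PhiST from pairwise distances with a permutation null.

    ``groups`` maps sample id -> group label.  Squared distances are
    decomposed into among- and within-group variance components
    (sigma_a, sigma_w); PhiST = sigma_a / (sigma_a + sigma_w).  The null
    shuffles group labels over samples.
    """
    if n_permutations < 99:
        raise ValueError("need >= 99 permutations")
    labels = np.array([groups[i] for i in dm.ids])
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise AmovaError("need >= 2 groups")
    for g in uniq:
        if (labels == g).sum() < 2:
            raise AmovaError(f"group {g!r} has fewer than 2 samples")
    n = len(dm.ids)
    d2 = dm.d**2
    idx = [np.flatnonzero(labels == g) for g in uniq]
    observed = _phi_from_d2(d2, idx, n)
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        pidx = [np.flatnonzero(perm == g) for g in uniq]
        if _phi_from_d2(d2, pidx, n) >= observed:
            b += 1
    p = (b + 1) / (n_permutations + 1)
    return FstResult(
        estimate=float(observed),
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed,
        flavor="phi_st_pairwise",
    )


def nj_tree_newick(dm: DistanceMatrix) -> str:
    """Neighbor-joining tree (newick, with branch lengths) from a distance
    matrix — a quick topology QC surrogate, not a model-based phylogeny."""
    if len(dm.ids) < 3:
        raise ValueError("need >= 3 samples for a tree")
    import skbio

    sk_dm = skbio.DistanceMatrix(dm.d, ids=dm.ids)
    tree = skbio.tree.nj(sk_dm)
    return str(tree).strip()
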