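"""Minimum Entropy Decomposition of aligned amplicon reads into oligotypes.

MED partitions one OTU's positionally homologous reads by recursively
splitting on the alignment column of highest Shannon entropy until the
residual entropy of every node falls below a threshold ``m``.  Terminal nodes
are oligotypes; nodes below a minimum substantive abundance are treated as
noise and either discarded or reassigned to the closest surviving oligotype.

Entropy at a column is computed over the five residue states ``A C G T -``
(gap is a real state); ``N`` is missing data and excluded from the frequency
denominator.  A read with ``N`` at a splitting column follows the majority
child.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sequences import N_CODE, RESIDUES, encode

__all__ = [
    "AlignedReadSet",
    "EntropyProfile",
    "Oligotype",
    "OligotypeCatalog",
    "column_entropy",
    "med_decompose",
    "build_count_matrix",
]


class AlignedReadSet:
    """Equal-length labelled amplicon reads for one OTU.

    Parameters
    ----------
    sequences, samples:
        Parallel lists: read sequences over ``ACGT-N`` and the sample/site
        label of each read.  All sequences must share one length.
    """

    def __init__(self, sequences: list[str], samples: list[str]):
        if not sequences:
            raise ValueError("read set is empty")
        if len(sequences) != len(samples):
            raise ValueError("sequences and samples differ in length")
        L = len(sequences[0])
        bad = [i for i, s in enumerate(sequences) if len(s) != L]
        if bad:
            raise ValueError(
                f"reads are not positionally homologous; offending records "
                f"(0-based): {bad[:10]}{'...' if len(bad) > 10 else ''}"
            )
        self.sequences = list(sequences)
        self.samples = list(samples)
        self.length = L
        self.sites = tuple(sorted(set(samples)))
        site_index = {s: j for j, s in enumerate(self.sites)}

        # collapse to unique sequences x sites
        uniq: dict[str, int] = {}
        rows: list[str] = []
        for s in sequences:
            if s not in uniq:
                uniq[s] = len(rows)
                rows.append(s)
        self.unique_sequences = rows
        self.counts = np.zeros((len(rows), len(self.sites)), dtype=np.int64)
        for s, lab in zip(sequences, samples):
            self.counts[uniq[s], site_index[lab]] += 1
        self.codes = encode(rows)

    @property
    def n_reads(self) -> int:
        return len(self.sequences)

    def __len__(self) -> int:
        return self.n_reads


@dataclass
class EntropyProfile:
    """Per-position Shannon entropy (bits) and residue counts."""

    entropy: np.ndarray  # length L, bits
    residue_counts: pd.DataFrame  # residues x positions

    def __len__(self) -> int:
        return len(self.entropy)


def _weighted_entropy(codes: np.ndarray, weights: np.ndarray):
    """Column entropies and residue counts for weighted unique sequences."""
    L = codes.shape[1]
    counts = np.zeros((len(RESIDUES), L), dtype=np.int64)
    for b in range(len(RESIDUES)):
        counts[b] = ((codes == b) * weights[:, None]).sum(axis=0)
    tot = counts.sum(axis=0).astype(float)
    p = np.where(tot > 0, counts / np.maximum(tot, 1), 0.0)
    logp = np.zeros_like(p)
    np.log2(p, out=logp, where=p > 0)
    h = -(p * logp).sum(axis=0)
    h[tot == 0] = 0.0
    return h, counts


def column_entropy(reads: AlignedReadSet) -> EntropyProfile:
    """Shannon entropy per alignment column over ``A C G T -`` (N excluded)."""
    weights = reads.counts.sum(axis=1)
    h, counts = _weighted_entropy(reads.codes, weights)
    if (counts.sum(axis=0) == 0).any():
        warnings.warn(
            "column(s) consisting entirely of N: entropy set to 0", stacklevel=2
        )
    return EntropyProfile(
        h, pd.DataFrame(counts, index=list(RESIDUES), columns=range(reads.length))
    )


@dataclass
class Oligotype:
    id: str
    sequence: str  # representative: most abundant unique sequence of the node
    positions: tuple[int, ...]  # discriminant positions used along the split path
    counts: dict[str, int]  # site -> read count

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class OligotypeCatalog:
    """Oligotypes with representatives and per-site counts, plus parameters."""

    oligotypes: list[Oligotype]
    sites: tuple[str, ...]
    params: dict
    n_input_reads: int
    n_filtered_reads: int = 0

    def __len__(self) -> int:
        return len(self.oligotypes)

    @property
    def total_counts(self) -> int:
        return sum(o.total for o in self.oligotypes)

    def sequences(self) -> list[str]:
        return [o.sequence for o in self.oligotypes]


def med_decompose(
    reads: AlignedReadSet,
    m: float = 0.0965,
    min_substantive_abundance: float | int = 0.01,
    d: int = 1,
    noise_policy: str = "reassign",
    max_oligotypes: int = 20000,
) -> OligotypeCatalog:
    """Decompose a read set into oligotypes by recursive entropy splitting.

    Parameters
    ----------
    m:
        Entropy threshold (bits) below which a node is terminal.
    min_substantive_abundance:
        Noise filter: a terminal node with fewer reads is removed.  Values
        < 1 are interpreted as a fraction of the input reads, values >= 1 as
        an absolute count.
    d:
        Number of highest-entropy positions used per split (ties broken by
        lowest position index).
    noise_policy:
        ``"reassign"`` moves each noise read to the surviving oligotype whose
        representative is nearest in Hamming distance (ties to the
        lexicographically smallest representative); ``"discard"`` drops them.
    """
    if m < 0:
        raise ValueError("entropy threshold m must be >= 0")
    if d < 1:
        raise ValueError("d must be >= 1")
    if noise_policy not in ("reassign", "discard"):
        raise ValueError("noise_policy must be 'reassign' or 'discard'")
    total_reads = reads.n_reads
    if min_substantive_abundance < 0 or (
        min_substantive_abundance >= 1 and min_substantive_abundance > total_reads
    ):
        raise ValueError("min_substantive_abundance out of range")
    m_min = (
        float(min_substantive_abundance) * total_reads
        if 0 <= min_substantive_abundance < 1
        else float(min_substantive_abundance)
    )

    codes = reads.codes
    counts = reads.counts
    weights = counts.sum(axis=1)

    terminals: list[tuple[np.ndarray, tuple[int, ...]]] = []
    stack: list[tuple[np.ndarray, tuple[int, ...]]] = [
        (np.arange(len(codes)), ())
    ]
    while stack:
        idx, used = stack.pop()
        h, _ = _weighted_entropy(codes[idx], weights[idx])
        if h.max() <= m:
            terminals.append((idx, used))
            continue
        # top-d positions by entropy, ties -> lowest index
        order = np.lexsort((np.arange(len(h)), -h))
        pos = tuple(int(p) for p in order[:d] if h[p] > m)
        if not pos:
            terminals.append((idx, used))
            continue
        keys = codes[np.ix_(idx, list(pos))]
        has_n = (keys == N_CODE).any(axis=1)
        groups: dict[tuple, list[int]] = {}
        for local, row in enumerate(keys):
            if has_n[local]:
                continue
            groups.setdefault(tuple(row), []).append(local)
        if not groups:
            terminals.append((idx, used))
            continue
        if has_n.any():
            # reads with N at a split position follow the majority child
            best = max(
                groups,
                key=lambda k: (weights[idx[groups[k]]].sum(), tuple(-int(x) for x in k)),
            )
            groups[best].extend(np.flatnonzero(has_n))
        children = [idx[sorted(loc)] for _, loc in sorted(groups.items())]
        if len(children) == 1:
            terminals.append((children[0], used + pos))
            continue
        if len(terminals) + len(stack) + len(children) > max_oligotypes:
            raise RuntimeError(
                f"node count exceeded {max_oligotypes}; the entropy threshold m={m} "
                "is too low for this data — increase m"
            )
        for child in children:
            stack.append((child, used + pos))

    # representatives and per-node tallies
    def representative(idx: np.ndarray) -> str:
        best = min(
            ((-weights[i], reads.unique_sequences[i]) for i in idx),
        )
        return best[1]

    nodes = []
    for idx, used in terminals:
        nodes.append(
            {
                "idx": idx,
                "positions": used,
                "rep": representative(idx),
                "site_counts": counts[idx].sum(axis=0),
            }
        )
    nodes.sort(key=lambda nd: (-nd["site_counts"].sum(), nd["rep"]))

    surviving = [nd for nd in nodes if nd["site_counts"].sum() >= m_min]
    noise = [nd for nd in nodes if nd["site_counts"].sum() < m_min]
    if not surviving:
        raise ValueError(
            "all nodes fall below the minimum substantive abundance; "
            "lower min_substantive_abundance"
        )

    n_filtered = 0
    if noise and noise_policy == "reassign":
        surv_codes = encode([nd["rep"] for nd in surviving])
        surv_order = np.lexsort(([nd["rep"] for nd in surviving],))
        for nd in noise:
            for i in nd["idx"]:
                seq_codes = codes[i]
                valid = (seq_codes != N_CODE) & (surv_codes != N_CODE)
                dists = ((surv_codes != seq_codes) & valid).sum(axis=1)
                dmin = dists.min()
                tied = np.flatnonzero(dists == dmin)
                # ties -> lexicographically smallest representative
                target = min(tied, key=lambda t: surviving[t]["rep"])
                surviving[target]["site_counts"] = (
                    surviving[target]["site_counts"] + counts[i]
                )
    elif noise:
        n_filtered = int(sum(nd["site_counts"].sum() for nd in noise))

    width = max(3, len(str(len(surviving))))
    oligos = [
        Oligotype(
            id=f"OT{j + 1:0{width}d}",
            sequence=nd["rep"],
            positions=nd["positions"],
            counts={
                s: int(c) for s, c in zip(reads.sites, nd["site_counts"]) if c > 0
            },
        )
        for j, nd in enumerate(surviving)
    ]
    return OligotypeCatalog(
        oligotypes=oligos,
        sites=reads.sites,
        params={
            "m": m,
            "min_substantive_abundance": min_substantive_abundance,
            "d": d,
            "noise_policy": noise_policy,
        },
        n_input_reads=total_reads,
        n_filtered_reads=n_filtered,
    )


def build_count_matrix(
    catalog: OligotypeCatalog, site_order: list[str] | None = None
) -> pd.DataFrame:
    """Oligotype x site integer count matrix in a stated row/column order."""
    if not catalog.oligotypes:
        raise ValueError("catalog is empty")
    if site_order is None:
        site_order = list(catalog.sites)
    unknown = [s for s in site_order if s not in catalog.sites]
    if unknown:
        raise ValueError(f"unknown site(s) in site_order: {unknown}")
    mat = pd.DataFrame(
        0,
        index=[o.id for o in catalog.oligotypes],
        columns=list(site_order),
        dtype=np.int64,
    )
    for o in catalog.oligotypes:
        for s, c in o.counts.items():
            if s in mat.columns:
                mat.loc[o.id, s] = c
    mat = mat.loc[(mat.sum(axis=1) > 0)]
    return mat
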