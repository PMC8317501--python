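"""Structured-coalescent synthetic data with known population structure.

Generates per-OTU aligned amplicon read sets whose true genealogy, haplotypes
and migration history are known, so every downstream statistic can be checked
against ground truth.  The model is a backward-time structured coalescent over
``n_demes`` island populations:

* within deme *i* holding ``n_i`` lineages, coalescences occur at total rate
  ``n_i (n_i - 1) / theta_i``;
* each lineage in deme *i* migrates (backward in time) to deme *j* at rate
  ``M[i][j] / 2``;
* waiting times are exponential; participants are chosen uniformly.

Mutations are dropped on the genealogy as a Poisson process with rate
``theta / 2`` per branch-length unit under a finite-sites model: each mutation
hits a uniformly chosen site and substitutes a uniformly chosen *different*
base, so recurrent hits are possible and the alignment length is preserved.
Reads are drawn multinomially from the per-deme haplotype frequencies and
corrupted site-wise with iid substitution errors.

Under this scaling the expected pairwise coalescence time in a single deme is
``theta/2`` and the expected number of pairwise sequence differences is
``theta^2/2``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "ScenarioConfig",
    "Genealogy",
    "TruthTable",
    "ReadSample",
    "DisconnectedHistoryError",
    "simulate_genealogy",
    "drop_mutations",
    "sample_reads",
    "generate_dataset",
    "barrier_scenario",
    "panmictic_scenario",
    "synthetic_environment",
]

BASES = "ACGT"

#: the four study sites: id, province, latitude, longitude (decimal degrees)
STUDY_SITES = (
    ("KGI", "Maritime Antarctica", -62.2154, -58.9455),
    ("PAT1", "Patagonia", -52.3314, -69.4863),
    ("PAT2", "Patagonia", -47.7519, -65.8678),
    ("KER", "Kerguelen Islands", -49.3537, 70.2191),
)

#: environmental variables emulated by the synthetic environment table
ENV_VARIABLES = (
    "ph",
    "nitrate",
    "silicate",
    "phosphate",
    "salinity",
    "dissolved_oxygen",
    "temperature",
    "temperature_range",
    "chlorophyll",
)


class DisconnectedHistoryError(RuntimeError):
    """No event has positive rate but several lineages remain uncoalesced."""


@dataclass(frozen=True)
class ScenarioConfig:
    """Simulator truth: deme layout, theta, migration matrix, error model.

    ``migration[i][j]`` is the backward rate at which a lineage currently in
    deme ``i`` moves to deme ``j`` (each lineage migrates at ``M[i][j]/2``).
    ``theta`` may be a scalar (shared) or one value per deme.

    ``split_time``, if set, models vicariance: at that time (backward) all
    remaining lineages merge into a single panmictic ancestral pool with the
    mean theta, so demes separated by a complete dispersal barrier (zero
    migration) still share a common ancestor.  Without it, a migration matrix
    that cannot bring every lineage into one deme raises
    :class:`DisconnectedHistoryError`.
    """

    deme_labels: tuple[str, ...] = tuple(s[0] for s in STUDY_SITES)
    provinces: tuple[str, ...] = tuple(s[1] for s in STUDY_SITES)
    latitudes: tuple[float, ...] = tuple(s[2] for s in STUDY_SITES)
    longitudes: tuple[float, ...] = tuple(s[3] for s in STUDY_SITES)
    sample_depths: tuple[int, ...] = (31, 15, 10, 14)
    n_lineages_per_deme: int | tuple[int, ...] = 20
    theta: float | tuple[float, ...] = 2.0
    migration: tuple[tuple[float, ...], ...] = ()
    seq_length: int = 370
    error_rate: float = 0.001
    hosts_per_deme: tuple[int, ...] | None = None
    split_time: float | None = None
    seed: int = 0

    def __post_init__(self):
        n = self.n_demes
        if n < 1:
            raise ValueError("at least one deme required")
        if len(self.sample_depths) != n or any(d < 1 for d in self.sample_depths):
            raise ValueError("sample_depths must give one depth >= 1 per deme")
        if self.seq_length < 1:
            raise ValueError("seq_length must be >= 1")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must lie in [0, 1)")
        lv = self.lineage_vector()
        if len(lv) != n or (lv < 0).any() or lv.sum() < 1:
            raise ValueError(
                "n_lineages_per_deme must give >= 0 lineages per deme, >= 1 total"
            )
        if not self.migration:
            object.__setattr__(self, "migration", tuple((0.0,) * n for _ in range(n)))
        M = self.migration_matrix()
        if M.shape != (n, n):
            raise ValueError("migration matrix must be n_demes x n_demes")
        if (np.diag(M) != 0).any():
            raise ValueError("migration diagonal must be zero")
        if (M < 0).any() or (self.theta_vector() < 0).any():
            raise ValueError("rates must be non-negative")
        if self.hosts_per_deme is not None and (
            len(self.hosts_per_deme) != n or any(h < 1 for h in self.hosts_per_deme)
        ):
            raise ValueError("hosts_per_deme must give one count >= 1 per deme")
        if self.split_time is not None and self.split_time < 0:
            raise ValueError("split_time must be non-negative")

    @property
    def n_demes(self) -> int:
        return len(self.deme_labels)

    def lineage_vector(self) -> np.ndarray:
        k = self.n_lineages_per_deme
        if np.isscalar(k):
            return np.full(self.n_demes, int(k), dtype=np.int64)
        return np.asarray(k, dtype=np.int64)

    def theta_vector(self) -> np.ndarray:
        th = self.theta
        if np.isscalar(th):
            return np.full(self.n_demes, float(th))
        return np.asarray(th, dtype=float)

    def migration_matrix(self) -> np.ndarray:
        return np.asarray(self.migration, dtype=float)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["theta"] = (
            float(self.theta) if np.isscalar(self.theta) else list(map(float, self.theta))
        )
        d["migration"] = [list(map(float, row)) for row in self.migration]
        return d


@dataclass
class Genealogy:
    """Binary genealogy over sampled lineages, times in coalescent units.

    ``parent[i]`` indexes each node's parent (-1 at the root); nodes
    ``0..n_tips-1`` are tips at time 0 with ``tip_deme`` labels.
    """

    parent: np.ndarray
    time: np.ndarray
    tip_deme: np.ndarray  # deme index per tip
    n_tips: int

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    def branch_lengths(self) -> np.ndarray:
        bl = np.zeros_like(self.time)
        has_parent = self.parent >= 0
        bl[has_parent] = self.time[self.parent[has_parent]] - self.time[has_parent]
        return bl


@dataclass
class TruthTable:
    """True haplotypes and their per-deme lineage counts (before reads)."""

    haplotypes: dict[str, str]  # haplotype id -> sequence
    lineage_counts: "np.ndarray"  # haplotype x deme counts of sampled lineages
    deme_labels: tuple[str, ...]

    @property
    def sequences(self) -> list[str]:
        return list(self.haplotypes.values())


@dataclass
class ReadSample:
    """Sampled reads plus the pre-error haplotype read counts per sample."""

    sequences: list[str]
    samples: list[str]  # parallel to sequences
    truth_counts: "np.ndarray"  # haplotype x sample, before error injection
    sample_labels: tuple[str, ...]
    sample_site: dict[str, str]  # sample label -> deme/site id


def _assert_coalescible(M: np.ndarray, occupied: np.ndarray) -> None:
    """Raise unless all lineages can almost surely meet in one deme.

    Lineages are absorbed into closed communicating classes of the migration
    digraph; a single common ancestor is guaranteed iff exactly one closed
    class is reachable from the occupied demes.
    """
    n = M.shape[0]
    reach = (M > 0) | np.eye(n, dtype=bool)
    for _ in range(n):  # transitive closure
        reach = reach | (reach @ reach)
    reachable = reach[occupied].any(axis=0)
    closed_classes = set()
    for i in np.flatnonzero(reachable):
        cls = frozenset(np.flatnonzero(reach[i] & reach[:, i]))
        # closed: nothing outside the class is reachable from it
        if not (reach[i] & ~np.isin(np.arange(n), list(cls))).any():
            closed_classes.add(cls)
    if len(closed_classes) != 1:
        raise DisconnectedHistoryError(
            "disconnected history: the migration matrix cannot bring all "
            "lineages into a common deme (set split_time or add migration)"
        )


def simulate_genealogy(config: ScenarioConfig, rng: np.random.Generator) -> Genealogy:
    """Run the structured coalescent backward until a single common ancestor.

    Raises :class:`DisconnectedHistoryError` if the lineages can never reach
    a common ancestor (e.g. zero migration with more than one occupied deme
    and no ``split_time``).
    """
    n_demes = config.n_demes
    theta = config.theta_vector()
    M = config.migration_matrix()
    lv = config.lineage_vector()
    n_tips = int(lv.sum())

    tip_deme = np.repeat(np.arange(n_demes), lv)
    # active lineage -> (node id, deme)
    active: list[list[int]] = [[] for _ in range(n_demes)]
    for node, deme in enumerate(tip_deme):
        active[deme].append(node)

    max_nodes = 2 * n_tips - 1
    parent = np.full(max_nodes, -1, dtype=np.int64)
    time = np.zeros(max_nodes, dtype=float)
    next_node = n_tips
    t = 0.0
    n_active = n_tips

    if n_tips == 1:
        return Genealogy(parent[:1], time[:1], tip_deme, 1)

    if config.split_time is None:
        _assert_coalescible(M, np.flatnonzero(lv > 0))
    split_time = math.inf if config.split_time is None else float(config.split_time)
    merged = False
    theta_anc = float(theta.mean()) if theta.size else 0.0

    mig_out = M / 2.0  # per-lineage rates

    while n_active > 1:
        counts = np.array([len(a) for a in active], dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            coal = np.where(theta > 0, counts * (counts - 1) / theta, 0.0)
        coal[counts < 2] = 0.0
        # demes with theta == 0 and >=2 lineages coalesce instantly
        instant = (theta == 0) & (counts >= 2)
        if instant.any():
            coal = np.where(instant, np.inf, coal)
        mig = counts[:, None] * mig_out  # deme i -> j total rates
        total = coal.sum() + mig.sum()
        if not np.isfinite(total):
            deme = int(np.flatnonzero(instant)[0])
            i1, i2 = rng.choice(len(active[deme]), size=2, replace=False)
        elif total <= 0 and merged:
            raise DisconnectedHistoryError(
                "disconnected history: ancestral pool has zero theta-rate"
            )
        else:
            wait = rng.exponential(1.0 / total) if total > 0 else math.inf
            if not merged and t + wait >= split_time:
                # vicariant merge: every lineage joins the ancestral pool
                t = split_time
                pool = [lin for deme_lins in active for lin in deme_lins]
                active = [[] for _ in range(n_demes)]
                active[0] = pool
                theta = np.full(n_demes, theta_anc if theta_anc > 0 else 1.0)
                mig_out = np.zeros_like(mig_out)
                merged = True
                continue
            t += wait
            u = rng.uniform(0, total)
            if u < coal.sum():
                deme = int(np.searchsorted(np.cumsum(coal), u, side="right"))
                i1, i2 = rng.choice(len(active[deme]), size=2, replace=False)
            else:
                u -= coal.sum()
                flat = int(np.searchsorted(np.cumsum(mig.ravel()), u, side="right"))
                src, dst = divmod(flat, n_demes)
                idx = int(rng.integers(len(active[src])))
                lin = active[src].pop(idx)
                active[dst].append(lin)
                continue
        # coalescence of two lineages in `deme`
        a, b = sorted((i1, i2), reverse=True)
        lin_b = active[deme].pop(a)
        lin_a = active[deme].pop(b)
        parent[lin_a] = next_node
        parent[lin_b] = next_node
        time[next_node] = t
        active[deme].append(next_node)
        next_node += 1
        n_active -= 1

    return Genealogy(parent[:next_node], time[:next_node], tip_deme, n_tips)


def drop_mutations(
    genealogy: Genealogy,
    theta: float,
    seq_length: int,
    rng: np.random.Generator,
    deme_labels: Sequence[str] | None = None,
) -> TruthTable:
    """Drop Poisson(theta/2 * branch length) finite-sites mutations.

    The root sequence is uniform random over ACGT; each mutation substitutes a
    uniformly chosen different base at a uniformly chosen site.
    """
    if theta < 0:
        raise ValueError("theta must be non-negative")
    n_nodes = len(genealogy.parent)
    n_tips = genealogy.n_tips
    bl = genealogy.branch_lengths()

    root_seq = rng.integers(0, 4, size=seq_length, dtype=np.uint8)
    seqs = np.empty((n_nodes, seq_length), dtype=np.uint8)
    seqs[genealogy.root] = root_seq

    children: list[list[int]] = [[] for _ in range(n_nodes)]
    for node, par in enumerate(genealogy.parent):
        if par >= 0:
            children[par].append(node)

    stack = [genealogy.root]
    while stack:
        node = stack.pop()
        for child in children[node]:
            seq = seqs[node].copy()
            n_mut = rng.poisson(theta / 2.0 * bl[child])
            for _ in range(n_mut):
                site = int(rng.integers(seq_length))
                seq[site] = (seq[site] + rng.integers(1, 4)) % 4
            seqs[child] = seq
            stack.append(child)

    base_lut = np.frombuffer(BASES.encode(), dtype=np.uint8)
    tip_strings = ["".join(map(chr, base_lut[seqs[i]])) for i in range(n_tips)]

    if deme_labels is None:
        n_demes = int(genealogy.tip_deme.max()) + 1 if n_tips else 0
        deme_labels = tuple(f"D{i}" for i in range(n_demes))
    n_demes = len(deme_labels)
    uniq = sorted(set(tip_strings))
    hap_index = {s: i for i, s in enumerate(uniq)}
    counts = np.zeros((len(uniq), n_demes), dtype=np.int64)
    for tip, seq in enumerate(tip_strings):
        counts[hap_index[seq], genealogy.tip_deme[tip]] += 1
    # order haplotypes by total abundance (desc), then sequence
    order = sorted(range(len(uniq)), key=lambda i: (-counts[i].sum(), uniq[i]))
    width = max(3, len(str(len(uniq))))
    haplotypes = {f"H{j + 1:0{width}d}": uniq[i] for j, i in enumerate(order)}
    return TruthTable(haplotypes, counts[order], tuple(deme_labels))


def sample_reads(
    truth: TruthTable, config: ScenarioConfig, rng: np.random.Generator
) -> ReadSample:
    """Draw per-deme reads multinomially and inject iid sequencing errors.

    With ``hosts_per_deme`` set, each deme's depth is split evenly (remainder
    to the first hosts) across per-host samples labelled ``SITE.hNN``.
    """
    if not 0 <= config.error_rate < 1:
        raise ValueError("error_rate must lie in [0, 1)")
    hap_seqs = truth.sequences
    n_hap = len(hap_seqs)
    L = config.seq_length

    sample_labels: list[str] = []
    sample_site: dict[str, str] = {}
    sample_depth: list[int] = []
    for d, label in enumerate(truth.deme_labels):
        depth = config.sample_depths[d]
        if config.hosts_per_deme is None:
            sample_labels.append(label)
            sample_site[label] = label
            sample_depth.append(depth)
        else:
            h = config.hosts_per_deme[d]
            base, extra = divmod(depth, h)
            for j in range(h):
                lab = f"{label}.h{j + 1:02d}"
                sample_labels.append(lab)
                sample_site[lab] = label
                sample_depth.append(base + (1 if j < extra else 0))

    truth_counts = np.zeros((n_hap, len(sample_labels)), dtype=np.int64)
    sequences: list[str] = []
    samples: list[str] = []

    enc = np.array([np.frombuffer(s.encode(), dtype=np.uint8) for s in hap_seqs])
    code = np.zeros(256, dtype=np.uint8)
    for i, c in enumerate(BASES):
        code[ord(c)] = i
    enc_codes = code[enc]
    base_lut = np.frombuffer(BASES.encode(), dtype=np.uint8)

    col = 0
    for d, label in enumerate(truth.deme_labels):
        freq = truth.lineage_counts[:, d].astype(float)
        tot = freq.sum()
        n_samples_here = (
            1 if config.hosts_per_deme is None else config.hosts_per_deme[d]
        )
        for _ in range(n_samples_here):
            depth = sample_depth[col]
            if tot == 0:
                col += 1
                continue
            draws = rng.multinomial(depth, freq / tot)
            truth_counts[:, col] = draws
            hap_idx = np.repeat(np.arange(n_hap), draws)
            reads = enc_codes[hap_idx].copy()
            if config.error_rate > 0 and depth > 0:
                err = rng.random((depth, L)) < config.error_rate
                n_err = int(err.sum())
                if n_err:
                    reads[err] = (reads[err] + rng.integers(1, 4, size=n_err)) % 4
            for r in reads:
                sequences.append("".join(map(chr, base_lut[r])))
                samples.append(sample_labels[col])
            col += 1

    return ReadSample(
        sequences, samples, truth_counts, tuple(sample_labels), sample_site
    )


def synthetic_environment(
    config: ScenarioConfig, rng: np.random.Generator
) -> "pd.DataFrame":
    """Per-site table of nine environmental variables.

    Values are province-level baselines (Antarctic sites cold, fresher, more
    oxygenated; sub-Antarctic intermediate) plus small site-level jitter, so
    the leading principal component separates provinces the way a real
    oceanographic climatology would.
    """
    import pandas as pd

    baselines = {
        "ph": 8.05,
        "nitrate": 22.0,
        "silicate": 30.0,
        "phosphate": 1.6,
        "salinity": 33.8,
        "dissolved_oxygen": 330.0,
        "temperature": 6.0,
        "temperature_range": 4.0,
        "chlorophyll": 0.6,
    }
    # severity of the polar signal per province
    severity = {
        "Maritime Antarctica": 1.0,
        "Kerguelen Islands": 0.45,
        "Patagonia": 0.0,
    }
    effect = {
        "ph": 0.1,
        "nitrate": 8.0,
        "silicate": 40.0,
        "phosphate": 0.5,
        "salinity": -0.9,
        "dissolved_oxygen": 40.0,
        "temperature": -7.5,
        "temperature_range": -2.0,
        "chlorophyll": -0.3,
    }
    rows = {}
    for label, prov in zip(config.deme_labels, config.provinces):
        s = severity.get(prov, 0.0)
        rows[label] = {
            v: baselines[v] + s * effect[v] + rng.normal(0, 0.02 * abs(effect[v]) + 1e-6)
            for v in ENV_VARIABLES
        }
    return pd.DataFrame.from_dict(rows, orient="index").loc[
        list(config.deme_labels), list(ENV_VARIABLES)
    ]


def _fanout(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def simulate_otu(config: ScenarioConfig, rng: np.random.Generator | None = None):
    """Genealogy -> haplotypes -> reads for one OTU. Returns (truth, sample)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    gen = simulate_genealogy(config, rng)
    th = float(np.mean(config.theta_vector()))
    truth = drop_mutations(gen, th, config.seq_length, rng, config.deme_labels)
    sample = sample_reads(truth, config, rng)
    return truth, sample


def generate_dataset(config: ScenarioConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write a fully reproducible dataset for one OTU under ``out_dir``.

    Emits the labelled read FASTA, truth tables (haplotype sequences, per-deme
    lineage counts, pre-error read counts), the site table, a synthetic
    environment table and the config used.  Identical (config, seed) produce
    byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    truth, sample = simulate_otu(config, _fanout(config.seed, 0))
    env = synthetic_environment(config, _fanout(config.seed, 1))

    paths = {
        "reads": out / "reads.fasta",
        "haplotypes": out / "truth_haplotypes.tsv",
        "lineage_counts": out / "truth_lineage_counts.tsv",
        "read_counts": out / "truth_read_counts.tsv",
        "sites": out / "sites.tsv",
        "environment": out / "environment.tsv",
        "config": out / "config.yaml",
    }

    with open(paths["reads"], "w") as fh:
        counter: dict[str, int] = {}
        for seq, sample_label in zip(sample.sequences, sample.samples):
            counter[sample_label] = counter.get(sample_label, 0) + 1
            fh.write(f">{sample_label}_{counter[sample_label]:06d}\n{seq}\n")

    with open(paths["haplotypes"], "w") as fh:
        fh.write("haplotype\tsequence\n")
        for hid, seq in truth.haplotypes.items():
            fh.write(f"{hid}\t{seq}\n")

    with open(paths["lineage_counts"], "w") as fh:
        fh.write("haplotype\t" + "\t".join(truth.deme_labels) + "\n")
        for i, hid in enumerate(truth.haplotypes):
            fh.write(hid + "\t" + "\t".join(map(str, truth.lineage_counts[i])) + "\n")

    with open(paths["read_counts"], "w") as fh:
        fh.write("haplotype\t" + "\t".join(sample.sample_labels) + "\n")
        for i, hid in enumerate(truth.haplotypes):
            fh.write(hid + "\t" + "\t".join(map(str, sample.truth_counts[i])) + "\n")

    with open(paths["sites"], "w") as fh:
        fh.write("site\tprovince\tlatitude\tlongitude\n")
        for lab, prov, lat, lon in zip(
            config.deme_labels, config.provinces, config.latitudes, config.longitudes
        ):
            fh.write(f"{lab}\t{prov}\t{lat}\t{lon}\n")

    with open(paths["environment"], "w") as fh:
        fh.write("site\t" + "\t".join(ENV_VARIABLES) + "\n")
        for lab in config.deme_labels:
            vals = "\t".join(f"{env.loc[lab, v]:.6f}" for v in ENV_VARIABLES)
            fh.write(f"{lab}\t{vals}\n")

    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    return paths


def barrier_scenario(
    sample_depths: tuple[int, ...] = (31, 15, 10, 14),
    n_lineages_per_deme: int = 20,
    theta: float = 2.0,
    within_m: float = 8.0,
    eastward_m: float = 2.0,
    cross_m: float = 0.0,
    seq_length: int = 370,
    error_rate: float = 0.001,
    hosts_per_deme: tuple[int, ...] | None = None,
    split_time: float | None = 8.0,
    seed: int = 0,
) -> ScenarioConfig:
    """Four-site scenario with a dispersal barrier isolating the Antarctic site.

    KGI (Maritime Antarctica) exchanges no migrants with the sub-Antarctic
    group (``cross_m``, default 0 — the polar-front barrier); the Patagonian
    pair is strongly connected (``within_m``); Kerguelen is linked to
    Patagonia with an eastward bias (``eastward_m`` forward KER->PAT flow,
    i.e. backward PAT->KER lineage movement, with a weak reverse leg).  The
    two groups share a vicariant ancestor at ``split_time`` (deep relative to
    the within-deme pairwise coalescence time theta/2).
    """
    labels = [s[0] for s in STUDY_SITES]
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    M = np.zeros((n, n))
    # barrier: KGI vs the rest
    for other in ("PAT1", "PAT2", "KER"):
        M[idx["KGI"], idx[other]] = cross_m
        M[idx[other], idx["KGI"]] = cross_m
    # strong within-province Patagonian connection
    M[idx["PAT1"], idx["PAT2"]] = within_m
    M[idx["PAT2"], idx["PAT1"]] = within_m
    # eastward circumpolar route: forward KER -> PAT means backward PAT -> KER
    M[idx["PAT1"], idx["KER"]] = eastward_m
    M[idx["PAT2"], idx["KER"]] = eastward_m
    M[idx["KER"], idx["PAT1"]] = eastward_m / 4.0
    M[idx["KER"], idx["PAT2"]] = eastward_m / 4.0
    return ScenarioConfig(
        sample_depths=tuple(sample_depths),
        n_lineages_per_deme=n_lineages_per_deme,
        theta=theta,
        migration=tuple(tuple(row) for row in M),
        seq_length=seq_length,
        error_rate=error_rate,
        hosts_per_deme=hosts_per_deme,
        split_time=split_time,
        seed=seed,
    )


def panmictic_scenario(
    n_demes: int = 2,
    depth: int = 50,
    n_lineages_per_deme: int = 20,
    theta: float = 2.0,
    m: float = 100.0,
    seq_length: int = 120,
    error_rate: float = 0.0,
    seed: int = 0,
) -> ScenarioConfig:
    """Symmetric island scenario; large ``m`` approximates panmixia."""
    M = np.full((n_demes, n_demes), m)
    np.fill_diagonal(M, 0.0)
    labels = tuple(f"S{i + 1}" for i in range(n_demes))
    return ScenarioConfig(
        deme_labels=labels,
        provinces=tuple("Province" for _ in labels),
        latitudes=tuple(-50.0 - i for i in range(n_demes)),
        longitudes=tuple(-60.0 + i for i in range(n_demes)),
        sample_depths=(depth,) * n_demes,
        n_lineages_per_deme=n_lineages_per_deme,
        theta=theta,
        migration=tuple(tuple(row) for row in M),
        seq_length=seq_length,
        error_rate=error_rate,
        seed=seed,
    )


def dataset_digest(paths: dict[str, Path]) -> dict[str, str]:
    """SHA-256 digests of generated files (manifest support)."""
    out = {}
    for key, p in sorted(paths.items()):
        out[key] = hashlib.sha256(Path(p).read_bytes()).hexdigest()
    return out
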