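"""End-to-end workflow: simulate -> oligotype -> popgen -> network ->
assembly -> matrix regression, with reproducible seeding and a manifest.

A single run seed is fanned out to per-stage generators through
``numpy.random.SeedSequence`` spawn keys (a counter-based scheme), so each
stage's randomness is independent of the others and a stage re-run with the
same seed reproduces its output exactly.  All tables are UTF-8 TSV with
header rows and floats at 4 decimals; outputs contain no timestamps, so a
repeated run with one seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assembly import (
    beta_nti,
    nj_tree,
    partition_processes,
    rc_bray,
)
from .hapnet import median_joining, node_weights
from .io import (
    read_labelled_fasta,
    read_tsv_matrix,
    write_catalog,
    write_network,
    write_tsv,
)
from .mmrr import (
    bray_curtis,
    env_pc1_distance,
    expand_site_matrix,
    great_circle_km,
    hellinger_rows,
    mmrr,
)
from .oligotyping import build_count_matrix, med_decompose
from .popgen import (
    diversity_indices,
    nm_island,
    pairwise_structure,
    rarefied_indices,
)
from .sequences import hamming_matrix
from .simulate import ScenarioConfig, barrier_scenario, generate_dataset

__all__ = ["RunConfig", "run_pipeline", "stage_rng", "site_of_sample"]

_STAGE_STREAMS = {
    "simulate": 0,
    "oligotype": 1,
    "popgen": 2,
    "network": 3,
    "assembly": 4,
    "mmrr": 5,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Per-stage generator from the run seed via a fixed spawn key."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STAGE_STREAMS[stage],))
    )


def site_of_sample(sample: str) -> str:
    """Site id of a sample label (per-host labels are ``SITE.hNN``)."""
    return sample.split(".h")[0]


@dataclass
class RunConfig:
    """Parameters of a full pipeline run."""

    out_dir: str | Path = "oligogeo_run"
    seed: int = 0
    # input: either a scenario to simulate or an existing labelled FASTA
    scenario: ScenarioConfig | None = None
    reads_fasta: str | Path | None = None
    sites_table: str | Path | None = None
    env_table: str | Path | None = None
    # oligotyping
    m: float = 0.0965
    min_substantive_abundance: float | int = 0.01
    d: int = 1
    noise_policy: str = "reassign"
    # popgen
    bootstrap: int = 200
    permutations: int = 199
    # network
    epsilon: float = 0.0
    # assembly
    null_reps: int = 199
    assembly_level: str = "sample"  # "sample" (per host) or "site" (pooled)
    # mmrr
    mmrr_permutations: int = 999
    hellinger_geography: bool = True

    def validate(self):
        if self.scenario is None and self.reads_fasta is None:
            raise ValueError("either a scenario or a reads FASTA is required")
        if self.reads_fasta is not None:
            for p, what in [
                (self.reads_fasta, "reads FASTA"),
                (self.sites_table, "site table"),
                (self.env_table, "environment table"),
            ]:
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(f"{what} not found: {p}")
            if self.sites_table is None:
                raise ValueError("site table required when reads are supplied")
            if self.env_table is None:
                raise ValueError("environment table required for the mmrr stage")
        if self.assembly_level not in ("sample", "site"):
            raise ValueError("assembly_level must be 'sample' or 'site'")


def demo_config(out_dir: str | Path, seed: int = 0) -> RunConfig:
    """The bundled barrier demonstration scenario.

    Four sites in three provinces, per-host read sampling, the polar-front
    barrier isolating the Antarctic site and an eastward route linking
    Kerguelen with Patagonia.
    """
    scenario = barrier_scenario(
        sample_depths=(310, 150, 100, 140),
        hosts_per_deme=(4, 3, 3, 3),
        n_lineages_per_deme=20,
        theta=2.0,
        error_rate=0.001,
        seed=seed,
    )
    return RunConfig(out_dir=out_dir, seed=seed, scenario=scenario)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns a result bundle of key objects.

    Every stage writes its TSV/FASTA/Newick outputs under ``out_dir`` and a
    ``manifest.json`` records version, parameters, seed and input digests.
    Stage failures propagate with the stage name in the message.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if k not in ("scenario", "out_dir")
        },
        "inputs": {},
        "stages": {},
    }
    for k, v in list(manifest["parameters"].items()):
        if isinstance(v, Path):
            manifest["parameters"][k] = str(v)

    def stage(name):
        def wrap(fn):
            try:
                fn()
            except Exception as exc:  # annotate with the stage name
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            manifest["stages"][name] = "ok"

        return wrap

    # ---------------------------------------------------------- simulate --
    if config.scenario is not None:
        scenario = dataclasses.replace(config.scenario, seed=config.seed)
        manifest["parameters"]["scenario"] = scenario.to_dict()

        @stage("simulate")
        def _simulate():
            data_dir = out / "data"
            paths = generate_dataset(scenario, data_dir)
            results["data_paths"] = paths
            manifest["inputs"] = {k: _digest(Path(p)) for k, p in sorted(paths.items())}

        reads_fasta = results["data_paths"]["reads"]
        sites_table = results["data_paths"]["sites"]
        env_table = results["data_paths"]["environment"]
    else:
        reads_fasta = Path(config.reads_fasta)
        sites_table = Path(config.sites_table)
        env_table = Path(config.env_table) if config.env_table else None
        manifest["inputs"] = {
            "reads": _digest(reads_fasta),
            "sites": _digest(sites_table),
            **({"environment": _digest(env_table)} if env_table else {}),
        }

    # --------------------------------------------------------- oligotype --
    @stage("oligotype")
    def _oligotype():
        reads = read_labelled_fasta(reads_fasta)
        catalog = med_decompose(
            reads,
            m=config.m,
            min_substantive_abundance=config.min_substantive_abundance,
            d=config.d,
            noise_policy=config.noise_policy,
        )
        results["catalog"] = catalog
        results["sample_counts"] = build_count_matrix(catalog)
        write_catalog(catalog, out / "oligotypes")

    sample_counts: pd.DataFrame = results["sample_counts"]
    catalog = results["catalog"]
    seqs = catalog.sequences()
    # aggregate per-host samples to sites for the population-level statistics
    site_map = {s: site_of_sample(s) for s in sample_counts.columns}
    site_counts = sample_counts.T.groupby(
        [site_map[s] for s in sample_counts.columns]
    ).sum().T
    site_counts = site_counts[sorted(site_counts.columns)]
    results["site_counts"] = site_counts

    # ------------------------------------------------------------ popgen --
    @stage("popgen")
    def _popgen():
        rng = stage_rng(config.seed, "popgen")
        div = diversity_indices(site_counts, seqs)
        write_tsv(div.table, out / "diversity_indices.tsv")
        rar = rarefied_indices(site_counts, seqs, B=config.bootstrap, rng=rng)
        write_tsv(rar.table, out / "diversity_indices_rarefied.tsv")
        struct = pairwise_structure(
            site_counts, seqs, P=config.permutations, rng=rng
        )
        # lower triangle = estimate, upper triangle = p-value
        for nm_, est, pv in (
            ("fst", struct.fst, struct.fst_p),
            ("phist", struct.phist, struct.phist_p),
        ):
            tab = est.copy()
            sites_ = list(tab.index)
            for a in range(len(sites_)):
                for b in range(a + 1, len(sites_)):
                    tab.iloc[a, b] = pv.iloc[a, b]
            write_tsv(tab, out / f"pairwise_{nm_}.tsv")
        nm_tab = struct.fst.copy()
        for a in range(len(nm_tab)):
            for b in range(len(nm_tab)):
                if a != b:
                    f = struct.fst.iloc[a, b]
                    nm_tab.iloc[a, b] = np.inf if f == 0 else nm_island(f)
        write_tsv(nm_tab, out / "nm_island_surrogate.tsv")
        with open(out / "snn.tsv", "w") as fh:
            fh.write("statistic\tvalue\n")
            fh.write(f"snn\t{struct.snn:.4f}\nsnn_p\t{struct.snn_p:.4f}\n")
        results["diversity"] = div
        results["diversity_rarefied"] = rar
        results["structure"] = struct

    # ----------------------------------------------------------- network --
    @stage("network")
    def _network():
        weights, freq = node_weights(site_counts)
        g = median_joining(
            seqs, weights=weights, epsilon=config.epsilon, composition=freq
        )
        results["network"] = g
        write_network(g, out / "network")

    # ---------------------------------------------------------- assembly --
    @stage("assembly")
    def _assembly():
        rng = stage_rng(config.seed, "assembly")
        comm = (
            sample_counts.T if config.assembly_level == "sample" else site_counts.T
        )
        comm = comm.loc[comm.sum(axis=1) > 0]
        ham = pd.DataFrame(
            hamming_matrix(seqs), index=sample_counts.index, columns=sample_counts.index
        )
        tree = nj_tree(ham)
        tree.write(str(out / "oligotype_nj.nwk"))
        bnti = beta_nti(comm, tree, reps=config.null_reps, rng=rng)
        rc = rc_bray(comm, reps=config.null_reps, rng=rng)
        write_tsv(bnti, out / "beta_nti.tsv")
        write_tsv(rc, out / "rc_bray.tsv")
        part = partition_processes(bnti, rc)
        frame = pd.DataFrame(
            {
                "fraction_pct": {
                    p: 100.0 * part.fractions[p] for p in part.fractions
                },
                "n_pairs": part.counts,
            }
        )
        write_tsv(frame, out / "process_partition.tsv")
        results["partition"] = part
        results["beta_nti"] = bnti
        results["rc_bray"] = rc

    # -------------------------------------------------------------- mmrr --
    @stage("mmrr")
    def _mmrr():
        rng = stage_rng(config.seed, "mmrr")
        sites_df = pd.read_csv(sites_table, sep="\t", index_col=0)
        env_df = pd.read_csv(env_table, sep="\t", index_col=0)
        geo = great_circle_km(sites_df)
        if config.hellinger_geography:
            geo = hellinger_rows(geo)
        envd, var_expl = env_pc1_distance(env_df)
        comm = sample_counts.T
        comm = comm.loc[comm.sum(axis=1) > 0]
        y = bray_curtis(comm)
        sample_site = {s: site_of_sample(s) for s in comm.index}
        X = {
            "IBE": expand_site_matrix(envd, sample_site),
            "IBD": expand_site_matrix(geo, sample_site),
        }
        fit = mmrr(y, X, perms=config.mmrr_permutations, rng=rng)
        write_tsv(fit.as_frame(), out / "mmrr.tsv")
        with open(out / "env_pca.tsv", "w") as fh:
            fh.write("statistic\tvalue\n")
            fh.write(f"pc1_variance_explained_pct\t{100 * var_expl:.4f}\n")
        results["mmrr"] = fit
        results["pc1_variance_explained"] = var_expl

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    results["manifest"] = manifest
    results["out_dir"] = out
    return results
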