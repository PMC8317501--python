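"""File formats: labelled FASTA, TSV tables, Newick and network exports.

Read headers follow the oligotyping sample-label dialect ``SAMPLE_READID``:
the sample id is everything before the *last* underscore.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .oligotyping import AlignedReadSet, OligotypeCatalog

__all__ = [
    "read_labelled_fasta",
    "write_labelled_fasta",
    "sample_from_header",
    "write_catalog",
    "read_tsv_matrix",
    "write_tsv",
    "write_network",
]

FLOAT_FORMAT = "%.4f"


def sample_from_header(header: str) -> str:
    """Sample id of a ``SAMPLE_READID`` header (last-underscore split)."""
    if "_" not in header:
        raise ValueError(f"unlabelled header (no underscore): {header!r}")
    return header.rsplit("_", 1)[0]


def read_labelled_fasta(path: str | Path) -> AlignedReadSet:
    """Read an aligned, sample-labelled FASTA into an :class:`AlignedReadSet`.

    Raises on ragged lengths (listing offending records) or headers without a
    sample label.
    """
    sequences: list[str] = []
    samples: list[str] = []
    headers: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        sequences.append(str(rec.seq).upper())
        samples.append(sample_from_header(rec.id))
        headers.append(rec.id)
    if not sequences:
        raise ValueError(f"no records in {path}")
    L = len(sequences[0])
    bad = [headers[i] for i, s in enumerate(sequences) if len(s) != L]
    if bad:
        raise ValueError(
            f"ragged read lengths in {path}; offending records: "
            f"{bad[:10]}{'...' if len(bad) > 10 else ''}"
        )
    return AlignedReadSet(sequences, samples)


def write_labelled_fasta(
    reads: AlignedReadSet, path: str | Path
) -> Path:
    """Write reads with ``SAMPLE_READN`` headers (per-sample counters)."""
    path = Path(path)
    counter: dict[str, int] = {}
    with open(path, "w") as fh:
        for seq, sample in zip(reads.sequences, reads.samples):
            counter[sample] = counter.get(sample, 0) + 1
            fh.write(f">{sample}_{counter[sample]:06d}\n{seq}\n")
    return path


def write_catalog(catalog: OligotypeCatalog, out_dir: str | Path) -> dict[str, Path]:
    """Write oligotype representatives (FASTA), counts (TSV) and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta = out / "oligotypes.fasta"
    with open(fasta, "w") as fh:
        for o in catalog.oligotypes:
            fh.write(f">{o.id}\n{o.sequence}\n")
    counts = out / "oligotype_counts.tsv"
    from .oligotyping import build_count_matrix

    build_count_matrix(catalog).to_csv(counts, sep="\t")
    manifest = out / "oligotyping_params.tsv"
    with open(manifest, "w") as fh:
        fh.write("parameter\tvalue\n")
        for kk, vv in sorted(catalog.params.items()):
            fh.write(f"{kk}\t{vv}\n")
        fh.write(f"n_input_reads\t{catalog.n_input_reads}\n")
        fh.write(f"n_filtered_reads\t{catalog.n_filtered_reads}\n")
        fh.write(f"n_oligotypes\t{len(catalog)}\n")
    return {"fasta": fasta, "counts": counts, "params": manifest}


def read_tsv_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_tsv(df: pd.DataFrame, path: str | Path, float_format: str = FLOAT_FORMAT):
    df.to_csv(path, sep="\t", float_format=float_format)
    return Path(path)


def write_network(g: nx.Graph, out_dir: str | Path, prefix: str = "network"):
    """Edge-list TSV, node table TSV and GraphML export of a haplotype network."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    edges = out / f"{prefix}_edges.tsv"
    with open(edges, "w") as fh:
        fh.write("node_a\tnode_b\tmutations\n")
        for a, b, data in sorted(g.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data['mutations']}\n")
    nodes = out / f"{prefix}_nodes.tsv"
    comp_sites: list[str] = []
    for _, data in g.nodes(data=True):
        comp = data.get("composition")
        if comp:
            comp_sites = sorted(comp)
            break
    with open(nodes, "w") as fh:
        head = "node\tsequence\tsampled\tweight"
        if comp_sites:
            head += "\t" + "\t".join(f"freq_{s}" for s in comp_sites)
        fh.write(head + "\n")
        for node, data in sorted(g.nodes(data=True)):
            row = (
                f"{node}\t{data['sequence']}\t{int(data['sampled'])}"
                f"\t{data['weight']:.4f}"
            )
            if comp_sites:
                comp = data.get("composition", {})
                row += "\t" + "\t".join(
                    f"{comp.get(s, 0.0):.4f}" for s in comp_sites
                )
            fh.write(row + "\n")
    gx = out / f"{prefix}.graphml"
    g2 = nx.Graph()
    for node, data in g.nodes(data=True):
        g2.add_node(
            node,
            sequence=data["sequence"],
            sampled=int(data["sampled"]),
            weight=float(data["weight"]),
        )
    for a, b, data in g.edges(data=True):
        g2.add_edge(a, b, mutations=int(data["mutations"]))
    nx.write_graphml(g2, gx)
    return {"edges": edges, "nodes": nodes, "graphml": gx}
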