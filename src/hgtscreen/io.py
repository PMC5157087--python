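"""Readers and writers for the pipeline's on-disk formats.

Genome and protein sets travel as FASTA (via Bio.SeqIO) with a side-car
lineage TSV (id, taxon, genus); gene models as GFF3 (1-based inclusive on
disk, 0-based half-open in memory); repeat masks as BED; coverage as
bedGraph; everything tabular as TSV.  Output tables carry ``#`` header lines
recording the tool version, seed, and a config hash so a rerun is verifiable
byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .famexpand import DomainCountMatrix
from .homology import ProteinRecord
from .screen import GeneModel
from .seqprep import GenomeSequence, MaskInterval

__all__ = [
    "write_fasta", "read_genome_fasta", "write_proteomes", "read_proteomes",
    "write_bed", "read_bed", "write_gff3", "read_gff3",
    "write_bedgraph", "read_bedgraph", "write_matrix_tsv", "read_matrix_tsv",
    "config_hash", "header_lines", "write_table", "write_bundle", "read_bundle",
]


def config_hash(obj) -> str:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def header_lines(seed: int | None = None, cfg_hash: str | None = None,
                 **extra) -> list[str]:
    lines = [f"# hgtscreen v{__version__}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    if cfg_hash is not None:
        lines.append(f"# config_sha={cfg_hash}")
    for k, v in sorted(extra.items()):
        lines.append(f"# {k}={v}")
    return lines


def write_table(df: pd.DataFrame, path, seed: int | None = None,
                cfg_hash: str | None = None, **extra) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_lines(seed, cfg_hash, **extra):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# --- FASTA -----------------------------------------------------------------

def write_fasta(path, items: list[tuple[str, str]]) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in items]
    SeqIO.write(records, str(path), "fasta")


def read_genome_fasta(path) -> list[GenomeSequence]:
    return [GenomeSequence(r.id, str(r.seq).upper())
            for r in SeqIO.parse(str(path), "fasta")]


def write_proteomes(outdir, proteomes: dict[str, list[ProteinRecord]],
                    genus_of: dict[str, str]) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for taxon in sorted(proteomes):
        recs = proteomes[taxon]
        write_fasta(outdir / f"{taxon}.fasta",
                    [(r.id, r.sequence) for r in recs])
        for r in recs:
            rows.append({"id": r.id, "taxon": taxon,
                         "genus": genus_of.get(r.id, r.lineage)})
    pd.DataFrame(rows).to_csv(outdir / "lineage.tsv", sep="\t", index=False)


def read_proteomes(outdir):
    outdir = Path(outdir)
    lineage = pd.read_csv(outdir / "lineage.tsv", sep="\t").fillna("")
    genus_of = dict(zip(lineage["id"], lineage["genus"]))
    taxon_of = dict(zip(lineage["id"], lineage["taxon"]))
    proteomes: dict[str, list[ProteinRecord]] = {}
    for fa in sorted(outdir.glob("*.fasta")):
        taxon = fa.stem
        proteomes[taxon] = [
            ProteinRecord(r.id, taxon_of.get(r.id, taxon), str(r.seq),
                          genus_of.get(r.id, ""))
            for r in SeqIO.parse(str(fa), "fasta")
        ]
    return proteomes, genus_of


# --- BED / GFF3 / bedGraph ---------------------------------------------------

def write_bed(path, masks: list[MaskInterval]) -> None:
    with open(path, "w") as fh:
        for m in masks:
            fh.write(f"{m.seq_id}\t{m.start}\t{m.end}\n")


def read_bed(path) -> list[MaskInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            seq_id, start, end = line.split()[:3]
            out.append(MaskInterval(seq_id, int(start), int(end)))
    return out


def write_gff3(path, genes: list[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.seq_id, g.start)):
            fh.write(f"{g.seq_id}\thgtscreen\tgene\t{g.start + 1}\t{g.end}\t."
                     f"\t{g.strand}\t.\tID={g.gene_id}\n")
            fh.write(f"{g.seq_id}\thgtscreen\tmRNA\t{g.start + 1}\t{g.end}\t."
                     f"\t{g.strand}\t.\tID={g.gene_id}.t1;Parent={g.gene_id}\n")
            for i, (a, b) in enumerate(g.exons, 1):
                for feat in ("exon", "CDS"):
                    fh.write(f"{g.seq_id}\thgtscreen\t{feat}\t{a + 1}\t{b}\t."
                             f"\t{g.strand}\t0\tID={g.gene_id}.{feat}{i};"
                             f"Parent={g.gene_id}.t1\n")


def read_gff3(path) -> list[GeneModel]:
    """Reconstruct gene models (CDS exons) from a GFF3 file."""
    cds: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            seq_id, _src, feat, start, end, _score, strand, _phase, attrs = parts
            if feat != "CDS":
                continue
            parent = dict(kv.split("=", 1) for kv in attrs.split(";"))["Parent"]
            gene_id = parent.rsplit(".t", 1)[0]
            d = cds.setdefault(gene_id,
                               {"seq_id": seq_id, "strand": strand, "exons": []})
            d["exons"].append((int(start) - 1, int(end)))
    return sorted(
        (GeneModel(gid, d["seq_id"], d["strand"], tuple(sorted(d["exons"])))
         for gid, d in cds.items()),
        key=lambda g: (g.seq_id, g.start))


def write_bedgraph(path, seq_id: str, values: np.ndarray) -> None:
    """Run-length compressed per-bp track."""
    with open(path, "w") as fh:
        if values.size == 0:
            return
        start = 0
        cur = values[0]
        for i in range(1, len(values)):
            if values[i] != cur:
                fh.write(f"{seq_id}\t{start}\t{i}\t{cur:g}\n")
                start, cur = i, values[i]
        fh.write(f"{seq_id}\t{start}\t{len(values)}\t{cur:g}\n")


def read_bedgraph(path, lengths: dict[str, int]) -> dict[str, np.ndarray]:
    tracks = {sid: np.zeros(n) for sid, n in lengths.items()}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            sid, a, b, v = line.split()
            if sid in tracks:
                tracks[sid][int(a):int(b)] = float(v)
    return tracks


# --- domain matrix -----------------------------------------------------------

def write_matrix_tsv(path, m: DomainCountMatrix) -> None:
    df = m.to_frame()
    df.insert(0, "species", df.index)
    with open(path, "w") as fh:
        fh.write(f"# focal={m.focal}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_matrix_tsv(path) -> DomainCountMatrix:
    focal = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# focal="):
            focal = first.strip().split("=", 1)[1]
    df = pd.read_csv(path, sep="\t", comment="#")
    species = tuple(df["species"])
    domains = tuple(df.columns[1:])
    counts = df.iloc[:, 1:].to_numpy(dtype=int)
    return DomainCountMatrix(species, domains, counts, focal or species[0])


# --- synthetic bundle round-trip --------------------------------------------

def write_bundle(bundle, outdir) -> None:
    """Materialise a synthetic bundle as the pipeline's input files."""
    from .simulate import Bundle  # local import to avoid cycle
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / "genome.fasta",
                [(bundle.genome.id, bundle.genome.residues)])
    write_bed(outdir / "mask.bed", bundle.masks)
    write_gff3(outdir / "genes.gff3", bundle.genes)
    write_proteomes(outdir / "proteomes", bundle.proteomes, bundle.genus_of)
    adj_rows = [{"a": sorted(k)[0], "b": sorted(k)[1]}
                for k, v in bundle.adjacency.items() if v]
    pd.DataFrame(adj_rows, columns=["a", "b"]).sort_values(
        ["a", "b"]).to_csv(outdir / "adjacency.tsv", sep="\t", index=False)
    write_bedgraph(outdir / "depth.bedgraph", bundle.genome.id, bundle.depth)
    write_bedgraph(outdir / "rna_plus.bedgraph", bundle.genome.id,
                   bundle.rna["+"])
    write_bedgraph(outdir / "rna_minus.bedgraph", bundle.genome.id,
                   bundle.rna["-"])
    pd.DataFrame(bundle.matepairs, columns=["seq_id", "left", "right"]).to_csv(
        outdir / "matepairs.tsv", sep="\t", index=False)
    bundle.truth.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    strands = pd.DataFrame(sorted(bundle.gene_strand.items()),
                           columns=["gene_id", "strand"])
    strands.to_csv(outdir / "gene_strands.tsv", sep="\t", index=False)
    write_matrix_tsv(outdir / "domain_counts.tsv", bundle.domain_matrix)
    pd.DataFrame({"domain": bundle.domain_truth}).to_csv(
        outdir / "domain_truth.tsv", sep="\t", index=False)
    with open(outdir / "config.json", "w") as fh:
        json.dump(dataclasses.asdict(bundle.cfg), fh, indent=1, sort_keys=True,
                  default=list)


def read_bundle(outdir):
    """Load a materialised bundle back into memory (truth tables included)."""
    from .simulate import Bundle, SynthConfig
    outdir = Path(outdir)
    with open(outdir / "config.json") as fh:
        raw = json.load(fh)
    for key in ("db_random_sizes",):
        raw[key] = tuple((t, int(n)) for t, n in raw[key])
    for key in ("protein_len", "intergenic_len", "intron_len",
                "domain_lambda_range"):
        raw[key] = tuple(raw[key])
    raw["unexpressed_genes"] = tuple(raw["unexpressed_genes"])
    cfg = SynthConfig(**raw)
    genome = read_genome_fasta(outdir / "genome.fasta")[0]
    masks = read_bed(outdir / "mask.bed")
    genes = read_gff3(outdir / "genes.gff3")
    proteomes, genus_of = read_proteomes(outdir / "proteomes")
    adj = pd.read_csv(outdir / "adjacency.tsv", sep="\t")
    adjacency = {frozenset((r.a, r.b)): True for r in adj.itertuples()}
    lengths = {genome.id: genome.length}
    depth = read_bedgraph(outdir / "depth.bedgraph", lengths)[genome.id]
    rna = {
        "+": read_bedgraph(outdir / "rna_plus.bedgraph", lengths)[genome.id],
        "-": read_bedgraph(outdir / "rna_minus.bedgraph", lengths)[genome.id],
    }
    mp = pd.read_csv(outdir / "matepairs.tsv", sep="\t")
    matepairs = [(r.seq_id, int(r.left), int(r.right)) for r in mp.itertuples()]
    truth = pd.read_csv(outdir / "truth_genes.tsv", sep="\t",
                        keep_default_na=False)
    strands = pd.read_csv(outdir / "gene_strands.tsv", sep="\t")
    gene_strand = dict(zip(strands["gene_id"], strands["strand"]))
    dom = read_matrix_tsv(outdir / "domain_counts.tsv")
    dom_truth = list(pd.read_csv(outdir / "domain_truth.tsv",
                                 sep="\t")["domain"])
    return Bundle(cfg, genome, masks, genes, gene_strand, proteomes, genus_of,
                  adjacency, truth, depth, matepairs, rna, dom, dom_truth)
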