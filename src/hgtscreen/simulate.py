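"""Seeded generator for every input the HGT pipeline consumes.

The generator emulates the statistical structure the screen assumes: an
insect-like host genome whose intrinsic genes have close homologs among
eukaryote database records, plus planted donor-derived genes back-translated
from bacterial/fungal database proteins at a controlled divergence.  Planted
architectures cover the cases of interest: spliceosomal introns (canonical
GT..AG), a fusion of two donor-adjacent genes into one host gene, adjacent
co-transferred gene pairs, and a duplicated pair with one member truncated.
Read-level evidence (Poisson depth, junction-spanning mate pairs, sense-strand
RNA coverage) and a species x domain count matrix with planted expansions are
generated alongside, each with an explicit truth table.

All outputs are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .famexpand import DomainCountMatrix
from .homology import ProteinRecord, TAXA
from .screen import GeneModel
from .seqprep import GenomeSequence, MaskInterval, translate_nt, reverse_complement

__all__ = ["SynthConfig", "Bundle", "generate_bundle", "gen_domain_matrix",
           "check_bundle"]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODONS_FOR: dict[str, list[str]] = {}
for _codon, _aa in sorted(_TABLE.forward_table.items()):
    _CODONS_FOR.setdefault(_aa, []).append(_codon)


@dataclass(frozen=True)
class SynthConfig:
    seed: int
    n_intrinsic_genes: int = 50
    n_hgt_bacterial: int = 6
    n_hgt_fungal: int = 4
    donor_divergence: float = 0.20
    intron_prob: float = 0.5
    n_fusions: int = 1
    n_cotransfer_pairs: int = 1
    n_truncated_dup_pairs: int = 1
    depth_mean: float = 30.0
    # database composition
    family_size: int = 3              # homologs per planted source protein
    within_taxon_divergence: float = 0.15
    distant_divergence: float = 0.50  # archaeal relatives of donor families
    db_random_sizes: tuple[tuple[str, int], ...] = (
        ("archaea", 12), ("bacteria", 15), ("fungi", 15),
        ("plants", 18), ("metazoa", 10), ("other_eukaryotes", 18),
    )
    protein_len: tuple[int, int] = (200, 280)
    fusion_component_len: int = 150
    truncated_fraction: float = 0.45
    # genome layout
    intergenic_len: tuple[int, int] = (200, 400)
    repeat_every: int = 8             # a masked repeat tract every k genes
    repeat_len: int = 150
    intron_len: tuple[int, int] = (60, 300)
    # read evidence
    matepair_per_junction: int = 8
    rna_depth: int = 5
    unexpressed_genes: tuple[str, ...] = ()
    # domain matrix
    n_species: int = 16
    n_domains: int = 200
    n_expanded_domains: int = 5
    expansion_effect: float = 4.0
    # background rates high enough that the planted effect size is
    # statistically identifiable against ~200-domain FDR control
    domain_lambda_range: tuple[float, float] = (15.0, 60.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.donor_divergence < 1.0:
            raise ValueError("donor_divergence must lie in [0,1)")
        extra = (self.n_fusions + 2 * self.n_cotransfer_pairs
                 + 2 * self.n_truncated_dup_pairs)
        if extra > self.n_hgt_bacterial:
            raise ValueError(
                "special architectures exceed n_hgt_bacterial "
                f"({extra} > {self.n_hgt_bacterial})")


@dataclass
class Bundle:
    """Everything the pipeline consumes, in memory, plus the truth tables."""

    cfg: SynthConfig
    genome: GenomeSequence
    masks: list[MaskInterval]
    genes: list[GeneModel]
    gene_strand: dict[str, str]
    proteomes: dict[str, list[ProteinRecord]]   # taxon -> records
    genus_of: dict[str, str]                    # record id -> genus
    adjacency: dict[frozenset, bool]            # donor-gene adjacency
    truth: pd.DataFrame                         # one row per planted gene
    depth: np.ndarray
    matepairs: list[tuple[str, int, int]]
    rna: dict[str, np.ndarray]                  # strand -> coverage
    domain_matrix: DomainCountMatrix
    domain_truth: list[str]

    @property
    def planted_hgt_ids(self) -> list[str]:
        return list(self.truth.loc[self.truth["cls"] == "hgt", "gene_id"])


def _random_protein(rng: np.random.Generator, length: int) -> str:
    pep = "M" + "".join(rng.choice(list(_AA), size=length - 1))
    return pep


def _mutate(pep: str, rate: float, rng: np.random.Generator,
            keep_start: bool = True) -> str:
    out = list(pep)
    for i in range(1 if keep_start else 0, len(out)):
        if rng.random() < rate:
            choices = [a for a in _AA if a != out[i]]
            out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def _back_translate(pep: str, rng: np.random.Generator) -> str:
    codons = []
    for aa in pep:
        opts = _CODONS_FOR[aa]
        codons.append(opts[rng.integers(0, len(opts))])
    return "".join(codons)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@dataclass
class _GeneSpec:
    gene_id: str
    cls: str                    # "intrinsic" | "hgt"
    protein: str
    donor_taxon: str = ""
    donor_genus: str = ""
    source_id: str = ""
    is_fusion: bool = False
    fusion_sources: tuple[str, str] | None = None
    cotransfer_partner: str = ""   # filled after layout
    truncated: bool = False
    pair_tag: str = ""             # genes sharing a tag stay adjacent


def _gen_proteomes(cfg: SynthConfig, rng: np.random.Generator):
    """Donor/background databases plus the planted gene blueprints."""
    proteomes: dict[str, list[ProteinRecord]] = {t: [] for t in TAXA}
    genus_of: dict[str, str] = {}
    adjacency: dict[frozenset, bool] = {}
    specs: list[_GeneSpec] = []

    def add_family(taxon: str, stem: str, genus: str, length: int) -> str:
        """Emit a source protein and its within-taxon family; return source id.

        Each family also gets distant archaeal relatives so validation trees
        contain out-of-kingdom leaves (archaea never enter the eukaryote
        background, so the h statistic is unaffected).
        """
        # a family ancestor with the source lineage on its own branch: the
        # planted host copy (at donor_divergence from the source) then nests
        # cleanly inside the donor clade, with archaea as a deeper sister
        # clade — the topology the validation stage is meant to recognise
        anc = _random_protein(rng, length)
        sid = f"{stem}_src"
        src = _mutate(anc, 0.10, rng)
        proteomes[taxon].append(ProteinRecord(sid, taxon, src, genus))
        genus_of[sid] = genus
        for k in range(cfg.family_size):
            div = 0.15 + 0.20 * rng.random()
            hid = f"{stem}_h{k}"
            proteomes[taxon].append(
                ProteinRecord(hid, taxon, _mutate(anc, div, rng), genus))
            genus_of[hid] = genus
        arc_root = _mutate(anc, cfg.distant_divergence, rng)
        for k in range(2):
            aid = f"{stem}_arc{k}"
            agenus = f"Arc{stem[:8]}"
            proteomes["archaea"].append(
                ProteinRecord(aid, "archaea", _mutate(arc_root, 0.10, rng),
                              agenus))
            genus_of[aid] = agenus
        return sid

    def source_seq(taxon: str, sid: str) -> str:
        for r in proteomes[taxon]:
            if r.id == sid:
                return r.sequence
        raise KeyError(sid)

    gene_no = 0

    def next_id() -> str:
        nonlocal gene_no
        gene_no += 1
        return f"gene{gene_no:05d}"

    plen = lambda: int(rng.integers(cfg.protein_len[0], cfg.protein_len[1] + 1))

    # --- bacterial architectures -----------------------------------------
    for i in range(cfg.n_fusions):
        genus = f"FusGenus{i:02d}"
        sa = add_family("bacteria", f"bac_fusA{i:02d}", genus,
                        cfg.fusion_component_len)
        sb = add_family("bacteria", f"bac_fusB{i:02d}", genus,
                        cfg.fusion_component_len)
        adjacency[frozenset((sa, sb))] = True
        fused = (_mutate(source_seq("bacteria", sa), cfg.donor_divergence, rng)
                 + _mutate(source_seq("bacteria", sb), cfg.donor_divergence,
                           rng, keep_start=False))
        specs.append(_GeneSpec(next_id(), "hgt", fused, "bacteria", genus, sa,
                               is_fusion=True, fusion_sources=(sa, sb)))

    for i in range(cfg.n_cotransfer_pairs):
        genus = f"CotGenus{i:02d}"
        sa = add_family("bacteria", f"bac_cotA{i:02d}", genus, plen())
        sb = add_family("bacteria", f"bac_cotB{i:02d}", genus, plen())
        adjacency[frozenset((sa, sb))] = True
        tag = f"cot{i:02d}"
        ga = _GeneSpec(next_id(), "hgt",
                       _mutate(source_seq("bacteria", sa),
                               cfg.donor_divergence, rng),
                       "bacteria", genus, sa, pair_tag=tag)
        gb = _GeneSpec(next_id(), "hgt",
                       _mutate(source_seq("bacteria", sb),
                               cfg.donor_divergence, rng),
                       "bacteria", genus, sb, pair_tag=tag)
        ga.cotransfer_partner, gb.cotransfer_partner = gb.gene_id, ga.gene_id
        specs.extend([ga, gb])

    for i in range(cfg.n_truncated_dup_pairs):
        genus = f"DupGenus{i:02d}"
        sa = add_family("bacteria", f"bac_dupA{i:02d}", genus, plen())
        sb = add_family("bacteria", f"bac_dupB{i:02d}", genus, plen())
        adjacency[frozenset((sa, sb))] = True
        tag = f"dup{i:02d}"
        pa = _mutate(source_seq("bacteria", sa), cfg.donor_divergence, rng)
        pb = _mutate(source_seq("bacteria", sb), cfg.donor_divergence, rng)
        # alternate which member is truncated across successive pairs
        trunc_first = (i % 2 == 0)
        if trunc_first:
            pa = pa[:max(60, int(len(pa) * cfg.truncated_fraction))]
        else:
            pb = pb[:max(60, int(len(pb) * cfg.truncated_fraction))]
        ga = _GeneSpec(next_id(), "hgt", pa, "bacteria", genus, sa,
                       truncated=trunc_first, pair_tag=tag)
        gb = _GeneSpec(next_id(), "hgt", pb, "bacteria", genus, sb,
                       truncated=not trunc_first, pair_tag=tag)
        ga.cotransfer_partner, gb.cotransfer_partner = gb.gene_id, ga.gene_id
        specs.extend([ga, gb])

    n_plain_bact = (cfg.n_hgt_bacterial - cfg.n_fusions
                    - 2 * cfg.n_cotransfer_pairs
                    - 2 * cfg.n_truncated_dup_pairs)
    for i in range(n_plain_bact):
        genus = f"BacGenus{i:02d}"
        s = add_family("bacteria", f"bac_plain{i:02d}", genus, plen())
        specs.append(_GeneSpec(next_id(), "hgt",
                               _mutate(source_seq("bacteria", s),
                                       cfg.donor_divergence, rng),
                               "bacteria", genus, s))

    for i in range(cfg.n_hgt_fungal):
        genus = f"FunGenus{i:02d}"
        s = add_family("fungi", f"fun_plain{i:02d}", genus, plen())
        specs.append(_GeneSpec(next_id(), "hgt",
                               _mutate(source_seq("fungi", s),
                                       cfg.donor_divergence, rng),
                               "fungi", genus, s))

    # --- intrinsic genes with eukaryote homologs -------------------------
    for i in range(cfg.n_intrinsic_genes):
        root = _random_protein(rng, plen())
        genus = f"MetGenus{i // 5:02d}"
        for k, div in enumerate((cfg.within_taxon_divergence, 0.30)):
            hid = f"met_hom{i:03d}_{k}"
            proteomes["metazoa"].append(
                ProteinRecord(hid, "metazoa", _mutate(root, div, rng), genus))
            genus_of[hid] = genus
        if i % 2 == 0:
            oid = f"oek_hom{i:03d}"
            proteomes["other_eukaryotes"].append(
                ProteinRecord(oid, "other_eukaryotes",
                              _mutate(root, 0.35, rng), f"OekGenus{i // 5:02d}"))
            genus_of[oid] = f"OekGenus{i // 5:02d}"
        specs.append(_GeneSpec(next_id(), "intrinsic",
                               _mutate(root, 0.10, rng)))

    # --- random database fill --------------------------------------------
    for taxon, nrand in cfg.db_random_sizes:
        for i in range(nrand):
            rid = f"{taxon[:3]}_rand{i:03d}"
            genus = f"{taxon[:3].capitalize()}Rand{i // 3:02d}"
            proteomes[taxon].append(
                ProteinRecord(rid, taxon, _random_protein(rng, plen()), genus))
            genus_of[rid] = genus
    return proteomes, genus_of, adjacency, specs


def _build_genome(cfg: SynthConfig, specs: list[_GeneSpec],
                  rng: np.random.Generator):
    """Lay out genes (pairs kept adjacent) with intergenic and repeat tracts."""
    # group genes into placement units so paired genes stay adjacent
    units: list[list[_GeneSpec]] = []
    by_tag: dict[str, list[_GeneSpec]] = {}
    for s in specs:
        if s.pair_tag:
            by_tag.setdefault(s.pair_tag, []).append(s)
        else:
            units.append([s])
    units.extend(by_tag.values())
    order = rng.permutation(len(units))
    units = [units[i] for i in order]

    seq_id = "scaf1"
    chunks: list[str] = []
    pos = 0
    masks: list[MaskInterval] = []
    genes: list[GeneModel] = []
    strand_of: dict[str, str] = {}
    rows = []
    n_placed = 0

    def spacer() -> None:
        nonlocal pos
        length = int(rng.integers(*cfg.intergenic_len))
        chunks.append(_random_dna(rng, length))
        pos += length

    spacer()
    for unit in units:
        for spec in unit:
            cds = _back_translate(spec.protein, rng) + "TAA"
            # decide intron placement at codon boundaries
            n_codons = len(cds) // 3
            intron_sites: list[int] = []
            if rng.random() < cfg.intron_prob and n_codons >= 150:
                n_int = int(rng.integers(1, 3))
                lo, hi = 70, n_codons - 70
                sites = sorted(rng.choice(np.arange(lo, hi), size=n_int,
                                          replace=False))
                # enforce >= 70 codons between introns
                pruned = []
                for s in sites:
                    if not pruned or s - pruned[-1] >= 70:
                        pruned.append(int(s))
                intron_sites = pruned
            gene_seq_parts = []
            exon_rel: list[tuple[int, int]] = []
            prev = 0
            cursor = 0
            for site in intron_sites:
                exon = cds[3 * prev:3 * site]
                gene_seq_parts.append(exon)
                exon_rel.append((cursor, cursor + len(exon)))
                cursor += len(exon)
                ilen = int(rng.integers(*cfg.intron_len))
                intron = "GT" + _random_dna(rng, ilen - 4) + "AG"
                gene_seq_parts.append(intron)
                cursor += len(intron)
                prev = site
            exon = cds[3 * prev:]
            gene_seq_parts.append(exon)
            exon_rel.append((cursor, cursor + len(exon)))
            gene_seq = "".join(gene_seq_parts)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                L = len(gene_seq)
                gene_seq = reverse_complement(gene_seq)
                exon_rel = sorted((L - b, L - a) for a, b in exon_rel)
            exons = tuple((pos + a, pos + b) for a, b in exon_rel)
            genes.append(GeneModel(spec.gene_id, seq_id, strand, exons))
            strand_of[spec.gene_id] = strand
            chunks.append(gene_seq)
            g_start, g_end = pos, pos + len(gene_seq)
            pos = g_end
            rows.append({
                "gene_id": spec.gene_id, "seq_id": seq_id,
                "start": g_start, "end": g_end, "strand": strand,
                "cls": spec.cls, "donor_taxon": spec.donor_taxon,
                "donor_genus": spec.donor_genus, "source_id": spec.source_id,
                "intron_count": len(exons) - 1,
                "is_fusion": spec.is_fusion,
                "fusion_sources": ",".join(spec.fusion_sources)
                if spec.fusion_sources else "",
                "cotransfer_partner": spec.cotransfer_partner,
                "truncated": spec.truncated,
            })
            # short spacer between paired genes, longer otherwise
            if spec is not unit[-1]:
                length = int(rng.integers(150, 300))
                chunks.append(_random_dna(rng, length))
                pos += length
        n_placed += 1
        if n_placed % cfg.repeat_every == 0:
            motif = _random_dna(rng, 25)
            tract = (motif * (cfg.repeat_len // len(motif) + 1))[:cfg.repeat_len]
            masks.append(MaskInterval(seq_id, pos, pos + len(tract)))
            chunks.append(tract)
            pos += len(tract)
        spacer()
    genome = GenomeSequence(seq_id, "".join(chunks))
    truth = pd.DataFrame(rows).sort_values("start").reset_index(drop=True)
    genes.sort(key=lambda g: g.start)
    return genome, masks, genes, strand_of, truth


def _gen_read_evidence(cfg: SynthConfig, genome: GenomeSequence,
                       genes: list[GeneModel], strand_of: dict[str, str],
                       rng: np.random.Generator):
    depth = rng.poisson(cfg.depth_mean, size=genome.length).astype(float)
    matepairs: list[tuple[str, int, int]] = []
    ordered = sorted(genes, key=lambda g: g.start)
    for left, right in zip(ordered, ordered[1:]):
        for _ in range(cfg.matepair_per_junction):
            a = int(rng.integers(left.start, left.end))
            b = int(rng.integers(right.start, right.end))
            matepairs.append((genome.id, min(a, b), max(a, b)))
    rna = {"+": np.zeros(genome.length), "-": np.zeros(genome.length)}
    for g in genes:
        if g.gene_id in cfg.unexpressed_genes:
            continue
        track = rna[strand_of[g.gene_id]]
        for a, b in g.exons:
            track[a:b] += cfg.rna_depth
    return depth, matepairs, rna


def gen_domain_matrix(cfg: SynthConfig, seed: int | None = None):
    """Species x domain counts with planted focal expansions.

    Background counts are Poisson with a per-domain rate shared across
    species; planted domains draw the focal count at ``expansion_effect``
    times that rate.  Returns (matrix, planted domain ids).
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    domains = tuple(f"IPR{j:05d}" for j in range(cfg.n_domains))
    species = ("focal",) + tuple(f"sp{j:02d}" for j in range(1, cfg.n_species))
    lam = rng.uniform(*cfg.domain_lambda_range, size=cfg.n_domains)
    counts = rng.poisson(lam[None, :].repeat(cfg.n_species, axis=0))
    planted = sorted(rng.choice(cfg.n_domains, size=cfg.n_expanded_domains,
                                replace=False))
    for j in planted:
        counts[0, j] = rng.poisson(lam[j] * cfg.expansion_effect)
    m = DomainCountMatrix(species, domains, counts.astype(int), "focal")
    return m, [domains[j] for j in planted]


def generate_bundle(cfg: SynthConfig) -> Bundle:
    """Generate the complete synthetic input bundle for one seed."""
    rng = np.random.default_rng(cfg.seed)
    proteomes, genus_of, adjacency, specs = _gen_proteomes(cfg, rng)
    genome, masks, genes, strand_of, truth = _build_genome(cfg, specs, rng)
    depth, matepairs, rna = _gen_read_evidence(cfg, genome, genes, strand_of,
                                               rng)
    dom_matrix, dom_truth = gen_domain_matrix(cfg, seed=cfg.seed + 1)
    bundle = Bundle(cfg, genome, masks, genes, strand_of, proteomes, genus_of,
                    adjacency, truth, depth, matepairs, rna, dom_matrix,
                    dom_truth)
    check_bundle(bundle)
    return bundle


def check_bundle(b: Bundle) -> None:
    """Internal consistency: truth vs annotations vs sequence content."""
    L = b.genome.length
    protein_of = {s: r.sequence for t in b.proteomes for r in b.proteomes[t]
                  for s in [r.id]}
    by_id = {g.gene_id: g for g in b.genes}
    for row in b.truth.itertuples():
        g = by_id[row.gene_id]
        assert 0 <= g.start < g.end <= L, f"{row.gene_id} out of bounds"
        assert g.cds_length % 3 == 0, f"{row.gene_id} CDS not codon-multiple"
        assert flag_count(g) == row.intron_count
        spliced = "".join(b.genome.residues[a:bb] for a, bb in g.exons)
        if b.gene_strand[row.gene_id] == "-":
            spliced = reverse_complement(spliced)
        pep = translate_nt(spliced)
        assert pep.endswith("*") and "*" not in pep[:-1], \
            f"{row.gene_id} has internal stops"
    for m in b.masks:
        assert m.end <= L
    assert (b.truth["cls"] == "hgt").sum() == (
        b.cfg.n_hgt_bacterial + b.cfg.n_hgt_fungal)


def flag_count(g: GeneModel) -> int:
    return len(g.exons) - 1
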