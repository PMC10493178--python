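"""Synthetic fixtures with planted, manifest-recorded truth.

Generates a toy genome (FASTA + index + chrom.sizes), gene models (the same
models emitted as both GTF and GFF3), a driver-gene list, a small signature
catalog, and replicated VCF cohorts whose summary statistics are *planted*:
class mix, 6-class substitution spectrum, indel-length distribution and
feature-category placement are realized by exact largest-remainder
allocation rather than sampling, so count-level summaries can be tested
against the manifest with zero tolerance. Replicates are built as a shared
core plus per-replicate private variants, which fixes the Venn structure by
construction. Only signature extraction/refitting uses stochastic (Poisson)
draws, via the matrix-level simulators at the bottom.

Everything is byte-reproducible from (spec, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pyfaidx import Faidx

from .annotate import CATEGORIES, AnnotationConfig
from .errors import ConfigError, GenerationError
from .signatures import CHANNELS, SBS96Matrix, write_signatures

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_CODE = {c: i for i, c in enumerate(CATEGORIES)}  # lower code = higher precedence


def allocate(n: int, probs: dict) -> dict:
    """Largest-remainder allocation of n items to categories by probability."""
    total = sum(probs.values())
    if total <= 0:
        raise ConfigError("allocation probabilities must sum to > 0")
    quotas = {k: n * v / total for k, v in probs.items()}
    counts = {k: int(q) for k, q in quotas.items()}
    short = n - sum(counts.values())
    # ties broken by insertion order of probs for determinism
    for k in sorted(quotas, key=lambda k: quotas[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


# --- genome ----------------------------------------------------------------


@dataclass
class GenomeFixture:
    fasta_path: Path
    sizes_path: Path
    sizes: dict[str, int]
    seqs: dict[str, str]


def make_genome(
    outdir: str | Path,
    seed: int,
    n_chroms: int = 2,
    chrom_len: int = 150_000,
) -> GenomeFixture:
    """Write a uniform-random ACGT toy genome with .fai index and chrom.sizes."""
    if chrom_len < 10_000:
        raise ConfigError("chrom_len must be >= 10000")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    seqs: dict[str, str] = {}
    fasta_path = outdir / "genome.fa"
    with open(fasta_path, "w") as fh:
        for i in range(n_chroms):
            name = f"chr{i + 1}"
            seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, chrom_len)])
            seqs[name] = seq
            fh.write(f">{name}\n")
            for j in range(0, chrom_len, 60):
                fh.write(seq[j : j + 60] + "\n")
    Faidx(str(fasta_path))
    sizes = {c: len(s) for c, s in seqs.items()}
    sizes_path = outdir / "chrom.sizes"
    sizes_path.write_text(
        "".join(f"{c}\t{l}\n" for c, l in sizes.items())
    )
    return GenomeFixture(fasta_path, sizes_path, sizes, seqs)


# --- gene models -----------------------------------------------------------


@dataclass
class TranscriptModel:
    tx_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    transcripts: list[TranscriptModel]


@dataclass
class ModelsFixture:
    gtf_path: Path
    gff3_path: Path
    genes: list[GeneModel]


def _make_transcript(
    rng: np.random.Generator, tx_id: str, start: int, end: int, strand: str
) -> TranscriptModel:
    """Exon chain spanning [start, end] with a CDS leaving UTRs on both sides."""
    n_exons = int(rng.integers(2, 7))
    span = end - start + 1
    # cut the span into alternating exon/intron segments
    n_cuts = 2 * n_exons - 1
    weights = rng.uniform(0.5, 1.5, n_cuts)
    lengths = np.maximum((weights / weights.sum() * span).astype(int), 60)
    lengths[-1] = span - int(lengths[:-1].sum())
    if lengths[-1] < 60:
        lengths = np.full(n_cuts, span // n_cuts)
        lengths[-1] = span - int(lengths[:-1].sum())
    exons = []
    pos = start
    for i, ln in enumerate(lengths):
        seg = (pos, pos + int(ln) - 1)
        if i % 2 == 0:
            exons.append(seg)
        pos += int(ln)
    # CDS from inside the first exon to inside the last exon (UTRs at both ends)
    first_s, first_e = exons[0]
    last_s, last_e = exons[-1]
    cds_lo = first_s + int(rng.integers(10, max(11, (first_e - first_s) // 2)))
    cds_hi = last_e - int(rng.integers(10, max(11, (last_e - last_s) // 2)))
    cds = []
    for s, e in exons:
        lo, hi = max(s, cds_lo), min(e, cds_hi)
        if lo <= hi:
            cds.append((lo, hi))
    return TranscriptModel(tx_id, strand, exons, cds)


def make_gene_models(
    genome: GenomeFixture,
    outdir: str | Path,
    seed: int,
    n_genes: int = 12,
    gene_span_range: tuple[int, int] = (4000, 9000),
    min_gap: int = 2600,
) -> ModelsFixture:
    """Place non-overlapping genes (flank-separated) and emit GTF + GFF3."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    chroms = list(genome.sizes)
    genes: list[GeneModel] = []
    per_chrom = [n_genes // len(chroms) + (1 if i < n_genes % len(chroms) else 0)
                 for i in range(len(chroms))]
    gi = 0
    for chrom, n_here in zip(chroms, per_chrom):
        cursor = min_gap
        L = genome.sizes[chrom]
        for _ in range(n_here):
            span = int(rng.integers(*gene_span_range))
            start = cursor + int(rng.integers(0, 800))
            end = start + span - 1
            if end > L - min_gap:
                raise GenerationError(
                    f"cannot place {n_here} genes of span ~{span} on {chrom} (len {L})"
                )
            gi += 1
            strand = "+" if rng.random() < 0.5 else "-"
            n_tx = int(rng.integers(1, 4))
            txs = [
                _make_transcript(rng, f"GENE{gi}.t{t + 1}", start, end, strand)
                for t in range(n_tx)
            ]
            genes.append(GeneModel(f"GENE{gi}", chrom, start, end, strand, txs))
            cursor = end + min_gap
    gtf_path = outdir / "models.gtf"
    gff3_path = outdir / "models.gff3"
    _write_gtf(genes, gtf_path)
    _write_gff3(genes, gff3_path)
    return ModelsFixture(gtf_path, gff3_path, genes)


def _write_gtf(genes: list[GeneModel], path: Path) -> None:
    lines = []
    for g in genes:
        attrs = f'gene_id "{g.gene_id}"; gene_name "{g.gene_id}";'
        lines.append(
            f"{g.chrom}\tfixture\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}"
        )
        for tx in g.transcripts:
            ta = attrs + f' transcript_id "{tx.tx_id}";'
            lines.append(
                f"{g.chrom}\tfixture\ttranscript\t{tx.start}\t{tx.end}\t.\t{g.strand}\t.\t{ta}"
            )
            for s, e in tx.exons:
                lines.append(
                    f"{g.chrom}\tfixture\texon\t{s}\t{e}\t.\t{g.strand}\t.\t{ta}"
                )
            for s, e in tx.cds:
                lines.append(
                    f"{g.chrom}\tfixture\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t{ta}"
                )
    path.write_text("\n".join(lines) + "\n")


def _write_gff3(genes: list[GeneModel], path: Path) -> None:
    lines = ["##gff-version 3"]
    for g in genes:
        lines.append(
            f"{g.chrom}\tfixture\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
            f"ID={g.gene_id};Name={g.gene_id}"
        )
        for tx in g.transcripts:
            lines.append(
                f"{g.chrom}\tfixture\tmRNA\t{tx.start}\t{tx.end}\t.\t{g.strand}\t.\t"
                f"ID={tx.tx_id};Parent={g.gene_id}"
            )
            for i, (s, e) in enumerate(tx.exons, 1):
                lines.append(
                    f"{g.chrom}\tfixture\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={tx.tx_id}.exon{i};Parent={tx.tx_id}"
                )
            for i, (s, e) in enumerate(tx.cds, 1):
                lines.append(
                    f"{g.chrom}\tfixture\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={tx.tx_id}.cds{i};Parent={tx.tx_id}"
                )
    path.write_text("\n".join(lines) + "\n")


# --- category painting ------------------------------------------------------


def paint_categories(
    sizes: dict[str, int],
    genes: list[GeneModel],
    cfg: AnnotationConfig | None = None,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Per-base feature-category codes and owning-gene indices per chromosome.

    An independent (array-painting) realization of the annotation precedence,
    used for planted placement and as a whole-genome oracle: arrays are
    1-based (index 0 unused); codes index into the category vocabulary,
    gene index is -1 where no gene owns the position.
    """
    cfg = cfg or AnnotationConfig()
    U, w = cfg.upstream_downstream_bp, cfg.splice_window_bp
    inter = _CODE["intergenic"]
    codes = {c: np.full(L + 1, inter, dtype=np.uint8) for c, L in sizes.items()}
    owner = {c: np.full(L + 1, -1, dtype=np.int32) for c, L in sizes.items()}
    for gidx, g in enumerate(genes):
        arr = codes[g.chrom]
        L = sizes[g.chrom]
        for tx in g.transcripts:
            tmp = np.full(L + 1, inter, dtype=np.uint8)
            tmp[tx.start : tx.end + 1] = _CODE["intronic"]
            for s, e in tx.exons:  # splice windows flanking each exon
                tmp[max(1, s - w) : s] = _CODE["splicing"]
                tmp[e + 1 : min(L, e + w) + 1] = _CODE["splicing"]
            exon_code = np.full(L + 1, 255, dtype=np.uint8)
            if tx.cds:
                lo = min(s for s, _ in tx.cds)
                hi = max(e for _, e in tx.cds)
                utr_left = "UTR5" if tx.strand == "+" else "UTR3"
                utr_right = "UTR3" if tx.strand == "+" else "UTR5"
                for s, e in tx.exons:
                    exon_code[s : e + 1] = _CODE["exonic"]
                    if s < lo:
                        exon_code[s : min(e, lo - 1) + 1] = _CODE[utr_left]
                    if e > hi:
                        exon_code[max(s, hi + 1) : e + 1] = _CODE[utr_right]
                    mid_lo, mid_hi = max(s, lo), min(e, hi)
                    if mid_lo <= mid_hi:
                        exon_code[mid_lo : mid_hi + 1] = _CODE["exonic"]
            else:
                for s, e in tx.exons:
                    exon_code[s : e + 1] = _CODE["exonic"]
            in_exon = exon_code != 255
            tmp[in_exon] = exon_code[in_exon]
            # splice windows never extend outside the transcript span
            tmp[: tx.start] = inter
            tmp[tx.end + 1 :] = inter
            up = "upstream" if tx.strand == "+" else "downstream"
            down = "downstream" if tx.strand == "+" else "upstream"
            tmp[max(1, tx.start - U) : tx.start] = _CODE[up]
            tmp[tx.end + 1 : min(L, tx.end + U) + 1] = _CODE[down]
            improved = tmp < arr
            arr[improved] = tmp[improved]
            owner[g.chrom][improved] = gidx
    return codes, owner


# --- cohort ----------------------------------------------------------------


@dataclass
class CohortSpec:
    """Planted study conditions for a replicated toy cohort."""

    groups: dict[str, int] = field(default_factory=lambda: {"tumor": 3, "normal": 3})
    n_core: int = 1400  # variants shared by all replicates of a group
    n_private: int = 600  # additional private variants per replicate
    class_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "SNV": 0.78,
            "INSERTION": 0.10,
            "DELETION": 0.10,
            "MNV": 0.02,
        }
    )
    spectrum6: dict[str, float] = field(
        default_factory=lambda: {
            "C>A": 0.10,
            "C>G": 0.08,
            "C>T": 0.40,
            "T>A": 0.07,
            "T>C": 0.25,
            "T>G": 0.10,
        }
    )
    indel_lengths: dict[int, float] = field(
        default_factory=lambda: {
            1: 0.45,
            2: 0.20,
            3: 0.12,
            4: 0.08,
            5: 0.05,
            7: 0.04,
            9: 0.03,
            12: 0.02,
            15: 0.01,
        }
    )
    category_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "exonic": 0.18,
            "splicing": 0.012,
            "UTR5": 0.04,
            "UTR3": 0.06,
            "intronic": 0.30,
            "upstream": 0.06,
            "downstream": 0.06,
            "intergenic": 0.288,
        }
    )
    n_driver_genes: int = 4
    window_bp: int = 50_000  # granularity of the manifest's window truth


@dataclass
class PlantedVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    vclass: str
    category: str
    gene: str | None
    channel: str | None  # SBS96 channel for SNVs


@dataclass
class CohortFixture:
    manifest: dict
    manifest_path: Path
    vcf_manifest: list[tuple[Path, str, str]]  # (path, group, sample)
    annotated_vcf_manifest: list[tuple[Path, str, str]]
    driver_path: Path


class _PositionPools:
    """Shuffled, globally-unique position pools keyed by category (and base)."""

    def __init__(
        self,
        seqs: dict[str, str],
        codes: dict[str, np.ndarray],
        owner: dict[str, np.ndarray],
        rng: np.random.Generator,
        max_del: int,
    ):
        self.seqs = seqs
        self.owner = owner
        self.used: set[tuple[str, int]] = set()
        self.pools: dict[tuple, list[tuple[str, int]]] = {}
        for chrom in sorted(seqs):
            seq = seqs[chrom]
            code = codes[chrom]
            L = len(seq)
            for pos in range(2, L):  # keep trinucleotide contexts complete
                cat = CATEGORIES[code[pos]]
                base = seq[pos - 1]
                group = "CG" if base in "CG" else "TA"
                self.pools.setdefault(("snv", cat, group), []).append((chrom, pos))
                if pos <= L - max_del - 1:
                    self.pools.setdefault(("indel", cat), []).append((chrom, pos))
        for key in self.pools:
            pool = self.pools[key]
            rng.shuffle(pool)

    def draw(self, key: tuple) -> tuple[str, int]:
        pool = self.pools.get(key, [])
        while pool:
            chrom, pos = pool.pop()
            if (chrom, pos) not in self.used:
                self.used.add((chrom, pos))
                return chrom, pos
        raise GenerationError(
            f"position pool exhausted for {key}: planted spec infeasible on this genome"
        )


def _snv_alleles(base: str, sub: str) -> tuple[str, str]:
    """Realize a 6-class substitution at a position with the given ref base."""
    ref6, alt6 = sub.split(">")
    if base == ref6:
        return ref6, alt6
    if base == ref6.translate(_COMPLEMENT):
        return base, alt6.translate(_COMPLEMENT)
    raise GenerationError(f"base {base} cannot carry substitution {sub}")


def _channel_of(seq: str, pos: int, ref: str, alt: str) -> str:
    tri = seq[pos - 2 : pos + 1].upper()
    if ref in "AG":
        tri = tri.translate(_COMPLEMENT)[::-1]
        ref = ref.translate(_COMPLEMENT)
        alt = alt.translate(_COMPLEMENT)
    return f"{tri[0]}[{ref}>{alt}]{tri[2]}"


def _plant_bundle(
    n: int, spec: CohortSpec, pools: _PositionPools, genes: list[GeneModel],
    rng: np.random.Generator,
) -> list[PlantedVariant]:
    """One exactly-allocated variant set (a replicate core or private set)."""
    by_class = allocate(n, spec.class_fractions)
    out: list[PlantedVariant] = []
    bases = "ACGT"

    def category_gene(chrom: str, pos: int) -> str | None:
        gidx = int(pools.owner[chrom][pos])
        return genes[gidx].gene_id if gidx >= 0 else None

    # SNVs: spectrum allocated globally (exact), categories per class
    for sub, m in allocate(by_class.get("SNV", 0), spec.spectrum6).items():
        for cat, c in allocate(m, spec.category_fractions).items():
            for _ in range(c):
                group = "CG" if sub.startswith("C") else "TA"
                chrom, pos = pools.draw(("snv", cat, group))
                seq = pools.seqs[chrom]
                ref, alt = _snv_alleles(seq[pos - 1], sub)
                out.append(
                    PlantedVariant(
                        chrom, pos, ref, alt, "SNV", cat,
                        category_gene(chrom, pos),
                        _channel_of(seq, pos, ref, alt),
                    )
                )
    # indels: lengths allocated globally per type, categories per length
    for vclass in ("INSERTION", "DELETION"):
        for length, m in allocate(by_class.get(vclass, 0), spec.indel_lengths).items():
            for cat, c in allocate(m, spec.category_fractions).items():
                for _ in range(c):
                    chrom, pos = pools.draw(("indel", cat))
                    seq = pools.seqs[chrom]
                    anchor = seq[pos - 1]
                    if vclass == "INSERTION":
                        ins = "".join(bases[i] for i in rng.integers(0, 4, length))
                        ref, alt = anchor, anchor + ins
                    else:
                        ref, alt = seq[pos - 1 : pos + length], anchor
                    out.append(
                        PlantedVariant(
                            chrom, pos, ref, alt, vclass, cat,
                            category_gene(chrom, pos), None,
                        )
                    )
    # MNVs: dinucleotide complemented in place (anchor-position category)
    for cat, c in allocate(by_class.get("MNV", 0), spec.category_fractions).items():
        for _ in range(c):
            chrom, pos = pools.draw(("indel", cat))
            seq = pools.seqs[chrom]
            ref = seq[pos - 1 : pos + 1]
            alt = ref.translate(_COMPLEMENT)
            out.append(
                PlantedVariant(
                    chrom, pos, ref, alt, "MNV", cat,
                    category_gene(chrom, pos), None,
                )
            )
    return out


def _write_sample_vcf(
    path: Path, variants: list[PlantedVariant], sizes: dict[str, int],
    annovar_info: bool,
) -> None:
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c},length={l}>" for c, l in sizes.items()]
    lines.append('##FILTER=<ID=PASS,Description="All filters passed">')
    if annovar_info:
        lines.append(
            '##INFO=<ID=Func.refGene,Number=.,Type=String,Description="feature">'
        )
        lines.append(
            '##INFO=<ID=Gene.refGene,Number=.,Type=String,Description="gene">'
        )
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
        if annovar_info:
            info = f"Func.refGene={v.category};Gene.refGene={v.gene or '.'}"
        else:
            info = "."
        lines.append(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}")
    path.write_text("\n".join(lines) + "\n")


def _sample_truth(
    variants: list[PlantedVariant], spec: CohortSpec, driver_genes: set[str]
) -> dict:
    class_counts = {c: 0 for c in ("SNV", "INSERTION", "DELETION", "MNV")}
    spectrum = {s: 0 for s in spec.spectrum6}
    ins_len: dict[str, int] = {}
    del_len: dict[str, int] = {}
    cats = {c: 0 for c in CATEGORIES}
    channels = {c: 0 for c in CHANNELS}
    drivers: dict[str, int] = {}
    windows: dict[str, int] = {}
    w = spec.window_bp
    driver_total = 0
    for v in variants:
        class_counts[v.vclass] += 1
        cats[v.category] += 1
        if v.vclass == "SNV":
            ref, alt = v.ref, v.alt
            if ref in "AG":
                ref = ref.translate(_COMPLEMENT)
                alt = alt.translate(_COMPLEMENT)
            spectrum[f"{ref}>{alt}"] += 1
            channels[v.channel] += 1
        elif v.vclass == "INSERTION":
            k = str(len(v.alt) - len(v.ref))
            ins_len[k] = ins_len.get(k, 0) + 1
        elif v.vclass == "DELETION":
            k = str(len(v.ref) - len(v.alt))
            del_len[k] = del_len.get(k, 0) + 1
        if v.vclass != "MNV":
            start = ((v.pos - 1) // w) * w + 1
            key = f"{v.chrom}:{start}:{'snv' if v.vclass == 'SNV' else 'indel'}"
            windows[key] = windows.get(key, 0) + 1
        in_gene = v.category in ("exonic", "splicing", "UTR5", "UTR3", "intronic")
        if in_gene and v.gene in driver_genes:
            drivers[v.gene] = drivers.get(v.gene, 0) + 1
            driver_total += 1
    return {
        "total": len(variants),
        "class_counts": class_counts,
        "spectrum6_counts": spectrum,
        "insertion_length_counts": ins_len,
        "deletion_length_counts": del_len,
        "category_counts": cats,
        "channel_counts": channels,
        "driver_gene_counts": drivers,
        "driver_total": driver_total,
        "window_counts": windows,
    }


def make_cohort(
    outdir: str | Path,
    genome: GenomeFixture,
    models: ModelsFixture,
    seed: int,
    spec: CohortSpec | None = None,
    ann_cfg: AnnotationConfig | None = None,
) -> CohortFixture:
    """Replicated VCF cohort with planted truth recorded in a manifest.

    Each group gets a shared core of ``spec.n_core`` variants plus
    ``spec.n_private`` private variants per replicate; all variant keys are
    unique within a group, so the Venn structure is exactly
    {all replicates: n_core, each replicate alone: n_private, rest: 0}.
    """
    spec = spec or CohortSpec()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    codes, owner = paint_categories(genome.sizes, models.genes, ann_cfg)
    max_del = max(spec.indel_lengths) if spec.indel_lengths else 1
    pools = _PositionPools(genome.seqs, codes, owner, rng, max_del)

    gene_ids = [g.gene_id for g in models.genes]
    n_drv = min(spec.n_driver_genes, len(gene_ids))
    driver_genes = sorted(rng.choice(gene_ids, size=n_drv, replace=False).tolist())
    driver_path = outdir / "driver_genes.tsv"
    driver_path.write_text("".join(g + "\n" for g in driver_genes))

    manifest: dict = {
        "seed": seed,
        "chrom_sizes": genome.sizes,
        "window_bp": spec.window_bp,
        "groups": {},
        "samples": {},
        "venn": {},
        "driver_genes": driver_genes,
        "gene_ids": gene_ids,
    }
    vcf_manifest: list[tuple[Path, str, str]] = []
    annotated_manifest: list[tuple[Path, str, str]] = []
    for group, n_rep in spec.groups.items():
        core = _plant_bundle(spec.n_core, spec, pools, models.genes, rng)
        sample_names = [f"{group}_rep{i + 1}" for i in range(n_rep)]
        manifest["groups"][group] = sample_names
        for sample in sample_names:
            private = _plant_bundle(spec.n_private, spec, pools, models.genes, rng)
            variants = core + private
            vcf_path = outdir / f"{sample}.vcf"
            ann_path = outdir / f"{sample}.annovar.vcf"
            _write_sample_vcf(vcf_path, variants, genome.sizes, annovar_info=False)
            _write_sample_vcf(ann_path, variants, genome.sizes, annovar_info=True)
            vcf_manifest.append((vcf_path, group, sample))
            annotated_manifest.append((ann_path, group, sample))
            manifest["samples"][sample] = _sample_truth(
                variants, spec, set(driver_genes)
            )
        venn: dict[str, int] = {}
        all_key = "&".join(sample_names)
        venn[all_key] = venn.get(all_key, 0) + spec.n_core
        for s in sample_names:
            venn[s] = venn.get(s, 0) + spec.n_private
        manifest["venn"][group] = venn

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return CohortFixture(
        manifest, manifest_path, vcf_manifest, annotated_manifest, driver_path
    )


def simulate_all(
    outdir: str | Path,
    seed: int,
    spec: CohortSpec | None = None,
    n_chroms: int = 2,
    chrom_len: int = 150_000,
    n_genes: int = 12,
) -> tuple[GenomeFixture, ModelsFixture, CohortFixture]:
    """Genome + gene models + cohort + signature catalog in one call."""
    outdir = Path(outdir)
    genome = make_genome(outdir, seed, n_chroms=n_chroms, chrom_len=chrom_len)
    models = make_gene_models(genome, outdir, seed + 1, n_genes=n_genes)
    cohort = make_cohort(outdir, genome, models, seed + 2, spec=spec)
    cat = make_signature_catalog(seed + 3)
    write_signatures(cat, outdir / "catalog.tsv")
    return genome, models, cohort


# --- signature-level simulators --------------------------------------------


def make_signature_catalog(
    seed: int, k: int = 4, background: float = 0.05
) -> pd.DataFrame:
    """Well-separated synthetic SBS96 signatures (pairwise cosine <= ~0.3).

    Each signature concentrates 1 - background of its mass on a private
    block of 96/k channels (random weights), with the rest spread uniformly,
    which keeps pairwise cosines low by construction.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(96)
    blocks = np.array_split(perm, k)
    W = np.full((96, k), background / 96)
    for j, block in enumerate(blocks):
        weights = rng.gamma(1.5, 1.0, size=len(block))
        W[block, j] += (1 - background) * weights / weights.sum()
    W /= W.sum(axis=0)
    return pd.DataFrame(
        W, index=list(CHANNELS), columns=[f"SynthSig{j + 1}" for j in range(k)]
    )


def make_exposures(
    n_samples: int, signatures: pd.DataFrame, total_per_sample: int, seed: int
) -> pd.DataFrame:
    """Random per-sample mixture fractions (Dirichlet) scaled to counts."""
    rng = np.random.default_rng(seed)
    k = signatures.shape[1]
    fracs = rng.dirichlet(np.ones(k), size=n_samples).T
    expo = fracs * total_per_sample
    return pd.DataFrame(
        expo,
        index=list(signatures.columns),
        columns=[f"S{i + 1}" for i in range(n_samples)],
    )


def simulate_sbs96_counts(
    signatures: pd.DataFrame,
    exposures: pd.DataFrame,
    seed: int,
    poisson: bool = True,
) -> SBS96Matrix:
    """Channel counts from planted mixtures, Poisson-noised or exact."""
    lam = signatures.to_numpy() @ exposures.to_numpy()
    if poisson:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(lam).astype(float)
    else:
        counts = lam
    df = pd.DataFrame(counts, index=list(CHANNELS), columns=list(exposures.columns))
    return SBS96Matrix(df, pd.Series(0, index=df.columns, dtype=int))
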