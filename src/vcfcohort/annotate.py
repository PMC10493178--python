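"""Native variant-to-gene-model feature annotation.

Assigns every variant exactly one genomic feature category relative to a
GTF/GFF3 gene model, with an Annovar-compatible precedence::

    exonic > splicing > UTR5 > UTR3 > intronic > upstream > downstream > intergenic

``exonic`` means inside the coding span of an exon (or any exon of a
non-coding transcript); ``splicing`` is an intronic position within
``splice_window_bp`` of an exon/intron boundary; upstream/downstream are
measured strand-aware from the transcript ends. Indels are annotated by
their anchor (leftmost) position. When several transcripts disagree the
highest-precedence category wins, and all gene names achieving it are
reported in lexicographic order.

If the VCF INFO already carries Annovar keys (``Func.refGene`` /
``Gene.refGene``) a parse mode maps them onto the same vocabulary instead
of re-annotating.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from intervaltree import IntervalTree

from .errors import ConfigError, FormatError
from .records import VariantRecord
from .vcf_io import Cohort

logger = logging.getLogger(__name__)

#: Feature vocabulary in precedence order (highest first).
CATEGORIES = (
    "exonic",
    "splicing",
    "UTR5",
    "UTR3",
    "intronic",
    "upstream",
    "downstream",
    "intergenic",
)
_RANK = {c: i for i, c in enumerate(CATEGORIES)}

#: Annovar Func.refGene vocabulary -> ours (fixed, documented mapping).
ANNOVAR_CATEGORY_MAP = {
    "exonic": "exonic",
    "exonic;splicing": "exonic",
    "splicing": "splicing",
    "ncRNA_exonic": "exonic",
    "ncRNA_splicing": "splicing",
    "ncRNA_intronic": "intronic",
    "UTR5": "UTR5",
    "UTR3": "UTR3",
    "intronic": "intronic",
    "upstream": "upstream",
    "downstream": "downstream",
    "upstream;downstream": "upstream",
    "intergenic": "intergenic",
}

# padding of the transcript interval tree; queries with a larger
# upstream/downstream window fall back to a linear scan
_TREE_PAD = 10_000


@dataclass
class AnnotationConfig:
    upstream_downstream_bp: int = 1000
    splice_window_bp: int = 2

    def __post_init__(self) -> None:
        if self.upstream_downstream_bp < 0 or self.splice_window_bp < 0:
            raise ConfigError("annotation windows must be non-negative")


@dataclass
class FeatureCall:
    category: str
    genes: list[str]
    distance: int = 0


@dataclass
class Transcript:
    tx_id: str
    gene: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    exons: list[tuple[int, int]]  # sorted by start
    cds: list[tuple[int, int]]

    @property
    def cds_span(self) -> tuple[int, int] | None:
        if not self.cds:
            return None
        return min(s for s, _ in self.cds), max(e for _, e in self.cds)


@dataclass
class GeneModelIndex:
    transcripts: list[Transcript]
    _trees: dict[str, IntervalTree] = field(default_factory=dict)
    _by_chrom: dict[str, list[Transcript]] = field(default_factory=dict)
    _gene_spans: dict[str, list[tuple[int, int, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        spans: dict[tuple[str, str], list[int]] = {}
        for tx in self.transcripts:
            self._by_chrom.setdefault(tx.chrom, []).append(tx)
            tree = self._trees.setdefault(tx.chrom, IntervalTree())
            # tree is 0-based half-open internally, padded for up/downstream
            tree[max(0, tx.start - 1 - _TREE_PAD): tx.end + _TREE_PAD] = tx
            key = (tx.chrom, tx.gene)
            span = spans.setdefault(key, [tx.start, tx.end])
            span[0] = min(span[0], tx.start)
            span[1] = max(span[1], tx.end)
        for (chrom, gene), (s, e) in spans.items():
            self._gene_spans.setdefault(chrom, []).append((s, e, gene))
        for chrom in self._gene_spans:
            self._gene_spans[chrom].sort()

    @property
    def n_transcripts(self) -> int:
        return len(self.transcripts)

    @property
    def genes(self) -> set[str]:
        return {tx.gene for tx in self.transcripts}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def chroms(self) -> set[str]:
        return set(self._by_chrom)

    def candidates(self, chrom: str, pos: int, reach: int) -> list[Transcript]:
        """Transcripts whose span is within ``reach`` bp of ``pos``."""
        if chrom not in self._by_chrom:
            return []
        if reach <= _TREE_PAD:
            hits = [iv.data for iv in self._trees[chrom][pos - 1]]
        else:
            hits = self._by_chrom[chrom]
        return [t for t in hits if t.start - reach <= pos <= t.end + reach]

    def flanking_genes(self, chrom: str, pos: int) -> tuple[list[str], int]:
        """Nearest gene name(s) left/right of an intergenic position."""
        spans = self._gene_spans.get(chrom, [])
        left: tuple[int, str] | None = None
        right: tuple[int, str] | None = None
        for s, e, gene in spans:
            if e < pos:
                d = pos - e
                if left is None or d < left[0]:
                    left = (d, gene)
            elif s > pos:
                d = s - pos
                if right is None or d < right[0]:
                    right = (d, gene)
        found = [x for x in (left, right) if x is not None]
        if not found:
            return [], 0
        dist = min(d for d, _ in found)
        return sorted({g for _, g in found}), dist


def _transcript_category(tx: Transcript, pos: int, cfg: AnnotationConfig) -> str | None:
    """Category of ``pos`` relative to one transcript, or None if out of reach."""
    if tx.start <= pos <= tx.end:
        in_exon = any(s <= pos <= e for s, e in tx.exons)
        if in_exon:
            span = tx.cds_span
            if span is None:
                return "exonic"
            lo, hi = span
            if lo <= pos <= hi:
                return "exonic"
            if pos < lo:
                return "UTR5" if tx.strand == "+" else "UTR3"
            return "UTR3" if tx.strand == "+" else "UTR5"
        # intronic: distance to the nearest exon boundary
        d = min(
            min(abs(pos - s), abs(pos - e)) for s, e in tx.exons
        )
        return "splicing" if d <= cfg.splice_window_bp else "intronic"
    # outside the span: upstream/downstream on the transcript's strand
    if pos < tx.start:
        gap = tx.start - pos
        side = "upstream" if tx.strand == "+" else "downstream"
    else:
        gap = pos - tx.end
        side = "downstream" if tx.strand == "+" else "upstream"
    if gap <= cfg.upstream_downstream_bp:
        return side
    return None


def annotate_position(
    chrom: str, pos: int, index: GeneModelIndex, cfg: AnnotationConfig | None = None
) -> FeatureCall:
    """Feature call for a bare genomic position (indel anchor semantics)."""
    cfg = cfg or AnnotationConfig()
    if chrom not in index.chroms():
        logger.warning("chromosome %s absent from gene-model index", chrom)
        return FeatureCall("intergenic", [], 0)
    best_rank = _RANK["intergenic"]
    genes: set[str] = set()
    gap = 0
    for tx in index.candidates(chrom, pos, cfg.upstream_downstream_bp):
        cat = _transcript_category(tx, pos, cfg)
        if cat is None:
            continue
        rank = _RANK[cat]
        if rank < best_rank:
            best_rank = rank
            genes = {tx.gene}
            gap = _distance_to_span(tx, pos)
        elif rank == best_rank:
            genes.add(tx.gene)
            gap = min(gap, _distance_to_span(tx, pos))
    if best_rank == _RANK["intergenic"]:
        flank_genes, dist = index.flanking_genes(chrom, pos)
        return FeatureCall("intergenic", flank_genes, dist)
    category = CATEGORIES[best_rank]
    distance = gap if category in ("upstream", "downstream") else 0
    return FeatureCall(category, sorted(genes), distance)


def _distance_to_span(tx: Transcript, pos: int) -> int:
    if tx.start <= pos <= tx.end:
        return 0
    return tx.start - pos if pos < tx.start else pos - tx.end


def annotate_variant(
    v: VariantRecord, index: GeneModelIndex, cfg: AnnotationConfig | None = None
) -> FeatureCall:
    return annotate_position(v.chrom, v.pos, index, cfg)


def feature_call_from_info(v: VariantRecord) -> FeatureCall | None:
    """Map Annovar-style INFO keys onto a FeatureCall; None if absent."""
    func = v.info.get("Func.refGene")
    if func is None:
        return None
    category = ANNOVAR_CATEGORY_MAP.get(func)
    if category is None:
        raise FormatError(f"unknown Annovar feature category {func!r}")
    genes = v.info.get("Gene.refGene", "")
    gene_list = sorted(g for g in genes.replace(";", ",").split(",") if g and g != ".")
    return FeatureCall(category, gene_list, 0)


def annotate_cohort(
    cohort: Cohort,
    index: GeneModelIndex | None = None,
    cfg: AnnotationConfig | None = None,
    prefer_info: bool = False,
) -> dict[str, list[FeatureCall]]:
    """Per-sample feature calls parallel to ``cohort.variants``.

    With ``prefer_info`` the Annovar parse mode is used wherever the INFO
    field carries the keys, falling back to native annotation otherwise.
    """
    if index is None and not prefer_info:
        raise ConfigError("need a gene-model index or prefer_info=True")
    out: dict[str, list[FeatureCall]] = {}
    for sample, recs in cohort.variants.items():
        calls = []
        for r in recs:
            call = feature_call_from_info(r) if prefer_info else None
            if call is None:
                if index is None:
                    raise ConfigError(
                        f"variant without Annovar INFO in sample {sample!r} "
                        "and no gene-model index supplied"
                    )
                call = annotate_variant(r, index, cfg)
            calls.append(call)
        out[sample] = calls
    return out


def load_gene_models(path: str | Path) -> GeneModelIndex:
    """Load a GTF (Ensembl dialect) or GFF3 file into a query index.

    Requires explicit transcript (or mRNA) features; UTRs are derived from
    CDS vs. exon extents, so explicit UTR lines are unnecessary.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse gene models ({exc})") from exc

    gene_names: dict[str, str] = {}
    for g in db.features_of_type("gene"):
        name = (
            g.attributes.get("gene_name", g.attributes.get("Name", [None]))[0]
            or g.attributes.get("gene_id", [g.id])[0]
        )
        gene_names[g.id] = name

    transcripts: list[Transcript] = []
    for tx in db.features_of_type(("transcript", "mRNA")):
        exons = sorted(
            (f.start, f.end) for f in db.children(tx, featuretype="exon")
        )
        if not exons:
            raise FormatError(f"transcript {tx.id} has no exons")
        for s, e in exons:
            if s < tx.start or e > tx.end:
                raise FormatError(
                    f"exon [{s},{e}] outside transcript {tx.id} span"
                )
        cds = sorted((f.start, f.end) for f in db.children(tx, featuretype="CDS"))
        gene = (
            tx.attributes.get("gene_name", [None])[0]
            or _parent_gene_name(tx, gene_names)
            or tx.attributes.get("gene_id", [tx.id])[0]
        )
        transcripts.append(
            Transcript(
                tx_id=tx.id,
                gene=gene,
                chrom=tx.seqid,
                start=tx.start,
                end=tx.end,
                strand=tx.strand if tx.strand in "+-" else "+",
                exons=exons,
                cds=cds,
            )
        )
    if not transcripts:
        raise FormatError(f"{path}: no transcript features found")
    _check_orphan_exons(db)
    return GeneModelIndex(transcripts)


def _parent_gene_name(tx, gene_names: dict[str, str]) -> str | None:
    for pid in tx.attributes.get("Parent", []):
        if pid in gene_names:
            return gene_names[pid]
    gid = tx.attributes.get("gene_id", [None])[0]
    return gene_names.get(gid)


def _check_orphan_exons(db) -> None:
    tx_ids = {t.id for t in db.features_of_type(("transcript", "mRNA"))}
    for ex in db.features_of_type("exon"):
        parents = set(ex.attributes.get("Parent", []))
        parents |= set(ex.attributes.get("transcript_id", []))
        if not (parents & tx_ids):
            raise FormatError(f"exon without parent transcript: {ex}")


def annotate_known_sites(
    variants: list[VariantRecord],
    sites_path: str | Path,
    fmt: str | None = None,
) -> list[tuple[bool, str | None]]:
    """Flag variants present in a known-sites table (dbSNP-style membership).

    BED files (0-based half-open ``chrom start end [id]``) match by position
    within the interval. TSV files (1-based) match by exact position —
     3 columns ``chrom pos id`` — or by position + alleles with 5 columns
    ``chrom pos ref alt id``. Format auto-detected from the extension,
    overridable with ``fmt`` ("bed" or "tsv").
    """
    sites_path = Path(sites_path)
    if fmt is None:
        fmt = "bed" if sites_path.suffix.lower() == ".bed" else "tsv"
    if fmt not in ("bed", "tsv"):
        raise ConfigError(f"unknown sites format {fmt!r}")

    trees: dict[str, IntervalTree] = {}
    exact: dict[tuple, str | None] = {}
    with open(sites_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            try:
                if fmt == "bed":
                    chrom, start, end = cols[0], int(cols[1]), int(cols[2])
                    site_id = cols[3] if len(cols) > 3 else None
                    if end <= start:
                        raise ValueError("empty interval")
                    trees.setdefault(chrom, IntervalTree())[start:end] = site_id
                elif len(cols) >= 5:
                    chrom, pos, ref, alt, site_id = cols[:5]
                    exact[(chrom, int(pos), ref.upper(), alt.upper())] = site_id
                elif len(cols) >= 2:
                    chrom, pos = cols[0], int(cols[1])
                    site_id = cols[2] if len(cols) > 2 else None
                    exact[(chrom, int(pos))] = site_id
                else:
                    raise ValueError("too few columns")
            except (ValueError, IndexError) as exc:
                raise FormatError(
                    f"{sites_path}:{lineno}: malformed sites line ({exc})"
                ) from exc

    out: list[tuple[bool, str | None]] = []
    for v in variants:
        hit: tuple[bool, str | None] = (False, None)
        if fmt == "bed":
            ivs = trees.get(v.chrom, IntervalTree())[v.pos - 1]
            if ivs:
                hit = (True, sorted(iv.data or "" for iv in ivs)[0] or None)
        else:
            key4 = (v.chrom, v.pos, v.ref, v.alt)
            if key4 in exact:
                hit = (True, exact[key4])
            elif (v.chrom, v.pos) in exact:
                hit = (True, exact[(v.chrom, v.pos)])
        out.append(hit)
    return out
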