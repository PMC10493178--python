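"""Cohort-level summary tables.

Each summary is a deterministic long-format :class:`pandas.DataFrame` with
columns ``sample, group, category, count, frequency`` (plus extras where
noted). Frequencies are always computed within-sample — each sample's rows
sum to 1 whenever the sample contributed at least one variant — unless
pooling across a group is explicitly requested.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotate import CATEGORIES, FeatureCall
from .errors import ConfigError
from .records import VariantClass, VariantKey, VariantRecord
from .vcf_io import Cohort

#: 12 raw substitution classes, reference-base major.
SUBSTITUTIONS_12 = tuple(
    f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a
)
#: 6 pyrimidine-reference classes (strand-collapsed).
SUBSTITUTIONS_6 = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Default indel-length bins as (lo, hi) with hi=None meaning open-ended.
DEFAULT_INDEL_BINS = ((1, 1), (2, 2), (3, 3), (4, 5), (6, 10), (11, None))


def collapse_substitution(sub: str) -> str:
    """Map a 12-class substitution onto its 6-class pyrimidine-reference form."""
    ref, alt = sub.split(">")
    if ref in "AG":
        ref, alt = ref.translate(_COMPLEMENT), alt.translate(_COMPLEMENT)
    return f"{ref}>{alt}"


def _iter_samples(cohort: Cohort) -> Iterable[tuple[str, str, list[VariantRecord]]]:
    for group, members in cohort.groups.items():
        for sample in members:
            yield sample, group, cohort.variants[sample]


def _freq_table(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=["sample", "group", "category", "count"])
    totals = df.groupby("sample")["count"].transform("sum")
    df["frequency"] = (df["count"] / totals.where(totals > 0)).fillna(0.0)
    return df


def count_variants(cohort: Cohort) -> pd.DataFrame:
    """Per-sample totals by class (total, SNV, insertion, deletion, MNV)."""
    order = ["total"] + [c.value for c in VariantClass]
    rows = []
    for sample, group, recs in _iter_samples(cohort):
        by_class = {c.value: 0 for c in VariantClass}
        for r in recs:
            by_class[r.vclass.value] += 1
        rows.append(
            {"sample": sample, "group": group, "category": "total", "count": len(recs)}
        )
        rows += [
            {"sample": sample, "group": group, "category": c, "count": by_class[c]}
            for c in by_class
        ]
    df = pd.DataFrame(rows, columns=["sample", "group", "category", "count"])
    df["category"] = pd.Categorical(df["category"], categories=order, ordered=True)
    return df.sort_values(["sample", "category"], kind="stable").reset_index(drop=True)


def replicate_overlap(cohort: Cohort, group: str) -> dict[frozenset, int]:
    """Exclusive Venn-region counts over a group's replicate key sets.

    Keys are matched allele-aware (chrom, pos, ref, alt). Returns a mapping
    from each non-empty subset of sample labels to the number of variant
    keys present in exactly that subset; the counts sum to the union size.
    """
    if group not in cohort.groups:
        raise ConfigError(f"unknown group {group!r}")
    members = cohort.groups[group]
    key_sets: dict[str, set[VariantKey]] = {
        s: {r.key for r in cohort.variants[s]} for s in members
    }
    regions: dict[frozenset, int] = {}
    for n in range(1, len(members) + 1):
        for subset in combinations(members, n):
            inside = set.intersection(*(key_sets[s] for s in subset))
            outside = set().union(
                *(key_sets[s] for s in members if s not in subset)
            ) if len(subset) < len(members) else set()
            regions[frozenset(subset)] = len(inside - outside)
    return regions


def overlap_table(cohort: Cohort, group: str) -> pd.DataFrame:
    """Venn regions as a table with '&'-joined sample subsets."""
    regions = replicate_overlap(cohort, group)
    order = cohort.groups[group]
    rows = [
        {
            "group": group,
            "subset": "&".join(s for s in order if s in subset),
            "n_samples": len(subset),
            "count": count,
        }
        for subset, count in regions.items()
    ]
    return (
        pd.DataFrame(rows)
        .sort_values(["n_samples", "subset"], kind="stable")
        .reset_index(drop=True)
    )


def substitution_spectrum(cohort: Cohort, collapse: bool = True) -> pd.DataFrame:
    """Base-substitution frequencies against each sample's total SNV background.

    ``collapse=True`` folds purine-reference changes onto the 6
    pyrimidine-reference classes by complementing both alleles;
    ``collapse=False`` keeps all 12 raw classes. MNVs and indels are ignored.
    """
    cats = SUBSTITUTIONS_6 if collapse else SUBSTITUTIONS_12
    rows = []
    for sample, group, recs in _iter_samples(cohort):
        counts = dict.fromkeys(cats, 0)
        for r in recs:
            if r.vclass is not VariantClass.SNV:
                continue
            sub = f"{r.ref}>{r.alt}"
            counts[collapse_substitution(sub) if collapse else sub] += 1
        rows += [
            {"sample": sample, "group": group, "category": c, "count": counts[c]}
            for c in cats
        ]
    return _freq_table(rows)


def _bin_label(lo: int, hi: int | None) -> str:
    if hi is None:
        return f">{lo - 1}"
    return str(lo) if lo == hi else f"{lo}-{hi}"


def resolve_bins(
    bin_edges: Sequence[int] | None,
) -> tuple[tuple[int, int | None], ...]:
    """Turn strictly increasing upper edges into (lo, hi) bins + open tail.

    ``[1, 2, 3, 5, 10]`` gives bins 1, 2, 3, 4-5, 6-10, >10 (the default).
    """
    if bin_edges is None:
        return DEFAULT_INDEL_BINS
    edges = list(bin_edges)
    if not edges or any(nxt <= prv for prv, nxt in zip(edges, edges[1:])) or edges[0] < 1:
        raise ConfigError(f"bin edges must be strictly increasing and >= 1: {edges}")
    bins: list[tuple[int, int | None]] = []
    lo = 1
    for hi in edges:
        bins.append((lo, hi))
        lo = hi + 1
    bins.append((lo, None))
    return tuple(bins)


def indel_length_distribution(
    cohort: Cohort, bin_edges: Sequence[int] | None = None
) -> pd.DataFrame:
    """Insertion and deletion length histograms per sample.

    Returns one long table with an ``indel_type`` column (INSERTION /
    DELETION); frequencies normalize within (sample, indel_type).
    """
    bins = resolve_bins(bin_edges)
    labels = [_bin_label(lo, hi) for lo, hi in bins]
    rows = []
    for sample, group, recs in _iter_samples(cohort):
        for itype in (VariantClass.INSERTION, VariantClass.DELETION):
            counts = dict.fromkeys(labels, 0)
            for r in recs:
                if r.vclass is not itype:
                    continue
                for (lo, hi), label in zip(bins, labels):
                    if lo <= r.indel_len and (hi is None or r.indel_len <= hi):
                        counts[label] += 1
                        break
            rows += [
                {
                    "sample": sample,
                    "group": group,
                    "indel_type": itype.value,
                    "category": label,
                    "count": counts[label],
                }
                for label in labels
            ]
    df = pd.DataFrame(
        rows, columns=["sample", "group", "indel_type", "category", "count"]
    )
    totals = df.groupby(["sample", "indel_type"])["count"].transform("sum")
    df["frequency"] = (df["count"] / totals.where(totals > 0)).fillna(0.0)
    return df


def genome_distribution(
    cohort: Cohort,
    chrom_sizes: Mapping[str, int],
    window_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Per-window SNV and indel counts (Circos-style track data).

    Windows tile each chromosome as [1, w], [w+1, 2w], ... with the last
    window truncated at the chromosome end. Variants on chromosomes absent
    from ``chrom_sizes`` land in an ``unplaced`` bucket.
    """
    if window_bp < 1:
        raise ConfigError("window_bp must be >= 1")
    rows = []
    for sample, group, recs in _iter_samples(cohort):
        grid: dict[tuple[str, int], list[int]] = {}
        for chrom, size in chrom_sizes.items():
            for start in range(1, size + 1, window_bp):
                grid[(chrom, start)] = [0, 0]
        unplaced = [0, 0]
        for r in recs:
            slot = 0 if r.vclass is VariantClass.SNV else 1
            if r.vclass is VariantClass.MNV:
                continue
            if r.chrom not in chrom_sizes:
                unplaced[slot] += 1
                continue
            start = ((r.pos - 1) // window_bp) * window_bp + 1
            grid[(r.chrom, start)][slot] += 1
        for (chrom, start), (n_snv, n_indel) in grid.items():
            end = min(start + window_bp - 1, chrom_sizes[chrom])
            rows.append(
                {
                    "chrom": chrom,
                    "window_start": start,
                    "window_end": end,
                    "sample": sample,
                    "group": group,
                    "snv_count": n_snv,
                    "indel_count": n_indel,
                }
            )
        if any(unplaced):
            rows.append(
                {
                    "chrom": "unplaced",
                    "window_start": 0,
                    "window_end": 0,
                    "sample": sample,
                    "group": group,
                    "snv_count": unplaced[0],
                    "indel_count": unplaced[1],
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "window_start",
            "window_end",
            "sample",
            "group",
            "snv_count",
            "indel_count",
        ],
    )


def _require_annotations(
    cohort: Cohort, annotations: Mapping[str, list[FeatureCall]]
) -> None:
    for sample in cohort.variants:
        calls = annotations.get(sample)
        if calls is None or len(calls) != len(cohort.variants[sample]):
            raise ConfigError(f"missing or incomplete annotation for sample {sample!r}")


def feature_distribution(
    cohort: Cohort, annotations: Mapping[str, list[FeatureCall]]
) -> pd.DataFrame:
    """Variant counts and frequencies per genomic feature category."""
    _require_annotations(cohort, annotations)
    rows = []
    for sample, group, recs in _iter_samples(cohort):
        counts = dict.fromkeys(CATEGORIES, 0)
        for call in annotations[sample]:
            counts[call.category] += 1
        rows += [
            {"sample": sample, "group": group, "category": c, "count": counts[c]}
            for c in CATEGORIES
        ]
    return _freq_table(rows)


#: Default genic categories for gene-level screens.
DEFAULT_GENIC_CATEGORIES = ("exonic", "splicing", "UTR5", "UTR3")

#: Categories where the variant lies inside the gene body (driver tallies).
IN_GENE_CATEGORIES = ("exonic", "splicing", "UTR5", "UTR3", "intronic")


def gene_mutation_ranking(
    cohort: Cohort,
    annotations: Mapping[str, list[FeatureCall]],
    categories: Sequence[str] = DEFAULT_GENIC_CATEGORIES,
    top_n: int = 20,
) -> pd.DataFrame:
    """High-frequency mutated genes per sample.

    Counts variants per gene restricted to ``categories``, ranks by
    descending count with lexicographic tie-break, keeps ``top_n`` rows
    per sample.
    """
    if top_n < 1:
        raise ConfigError("top_n must be >= 1")
    bad = set(categories) - set(CATEGORIES)
    if bad:
        raise ConfigError(f"unknown feature categories: {sorted(bad)}")
    _require_annotations(cohort, annotations)
    rows = []
    for sample, group, recs in _iter_samples(cohort):
        per_gene: dict[str, int] = {}
        for call in annotations[sample]:
            if call.category not in categories:
                continue
            for gene in call.genes:
                per_gene[gene] = per_gene.get(gene, 0) + 1
        ranked = sorted(per_gene.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
        rows += [
            {"sample": sample, "group": group, "gene": g, "count": n, "rank": i + 1}
            for i, (g, n) in enumerate(ranked)
        ]
    return pd.DataFrame(rows, columns=["sample", "group", "gene", "count", "rank"])


def driver_gene_tally(
    cohort: Cohort,
    annotations: Mapping[str, list[FeatureCall]],
    driver_genes: Iterable[str],
    categories: Sequence[str] = IN_GENE_CATEGORIES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts of variants located in listed cancer driver genes.

    Only variants whose feature category places them inside a gene body
    (``categories``, default exonic/splicing/UTR/intronic) are counted —
    upstream, downstream and intergenic calls name nearby genes without the
    variant being *in* them. Matching is exact and case-sensitive. Returns
    (per-gene table restricted to genes with >= 1 variant, per-sample
    totals table).
    """
    driver_set = set(driver_genes)
    if not driver_set:
        raise ConfigError("empty driver gene list")
    _require_annotations(cohort, annotations)
    gene_rows, total_rows = [], []
    for sample, group, recs in _iter_samples(cohort):
        per_gene: dict[str, int] = {}
        total = 0
        for call in annotations[sample]:
            if call.category not in categories:
                continue
            hit_genes = [g for g in call.genes if g in driver_set]
            if hit_genes:
                total += 1
            for g in hit_genes:
                per_gene[g] = per_gene.get(g, 0) + 1
        gene_rows += [
            {"sample": sample, "group": group, "gene": g, "count": n}
            for g, n in sorted(per_gene.items())
        ]
        total_rows.append(
            {"sample": sample, "group": group, "category": "in_driver", "count": total}
        )
    per_gene_df = pd.DataFrame(gene_rows, columns=["sample", "group", "gene", "count"])
    totals_df = pd.DataFrame(
        total_rows, columns=["sample", "group", "category", "count"]
    )
    return per_gene_df, totals_df


def write_tsv(df: pd.DataFrame, path) -> None:
    """Stable TSV writer: LF endings, fixed column order, no index."""
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.10g")
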