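"""VCF ingestion and cohort assembly.

Reading goes through :mod:`pysam` (plain or bgzip-compressed VCF v4.x).
Every (site, ALT allele) pair becomes one normalized :class:`VariantRecord`
after multi-allelic splitting; symbolic and breakend ALTs (``<DEL>``, ``*``,
``]..]``) are skipped and counted. A cohort is an explicit mapping of groups
to ordered replicate samples — grouping never comes from filename parsing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .errors import ConfigError, FormatError
from .records import VariantRecord, make_record

logger = logging.getLogger(__name__)

#: FILTER values treated as passing under ``pass_only``.
PASSING_FILTERS = frozenset({"PASS", "."})


@dataclass
class Cohort:
    """Named groups of replicate samples and their variant collections."""

    groups: dict[str, list[str]] = field(default_factory=dict)
    variants: dict[str, list[VariantRecord]] = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return [s for members in self.groups.values() for s in members]

    def group_of(self, sample: str) -> str:
        for group, members in self.groups.items():
            if sample in members:
                return group
        raise ConfigError(f"sample {sample!r} not in any group")

    def validate(self) -> None:
        seen: set[str] = set()
        for group, members in self.groups.items():
            if not members:
                raise ConfigError(f"group {group!r} has no samples")
            for s in members:
                if s in seen:
                    raise ConfigError(f"sample label {s!r} in more than one group")
                seen.add(s)
        missing = seen - set(self.variants)
        if missing:
            raise ConfigError(f"samples without variant lists: {sorted(missing)}")


def _is_symbolic(alt: str) -> bool:
    return any(c in alt for c in "<>[]*.") or alt == ""


def read_vcf(
    path: str | Path,
    sample_label: str | None = None,
    pass_only: bool = True,
) -> list[VariantRecord]:
    """Read one VCF into normalized, classified records.

    Parameters
    ----------
    path:
        Plain or bgzipped VCF v4.x with a header.
    sample_label:
        Label attached to the records when the VCF carries no genotype
        columns (site-only VCF) or exactly one sample column. Defaults to
        the file stem. Multi-sample VCFs ignore it: each VCF sample column
        becomes its own label and a variant is attributed to every sample
        with a non-reference genotype call.
    pass_only:
        Keep only records whose FILTER is ``PASS`` or ``.``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    label = sample_label if sample_label is not None else path.stem
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"{path}: not a readable VCF ({exc})") from exc
    records: list[VariantRecord] = []
    n_symbolic = 0
    with vf:
        vcf_samples = list(vf.header.samples)
        for rec in vf:
            filters = list(rec.filter.keys())
            filter_pass = not filters or all(f in PASSING_FILTERS for f in filters)
            if pass_only and not filter_pass:
                continue
            if rec.alts is None:
                continue
            info = {
                k: (",".join(map(str, v)) if isinstance(v, tuple) else str(v))
                for k, v in rec.info.items()
            }
            if len(vcf_samples) > 1:
                carriers = [
                    s
                    for s in vcf_samples
                    if any(a not in (0, None) for a in (rec.samples[s].get("GT") or ()))
                ]
            else:
                carriers = [label]
            for alt in rec.alts:
                if alt is None or _is_symbolic(alt):
                    n_symbolic += 1
                    continue
                for carrier in carriers:
                    records.append(
                        make_record(
                            rec.chrom,
                            rec.pos,
                            rec.ref,
                            alt,
                            sample=carrier,
                            filter_pass=filter_pass,
                            info=info,
                        )
                    )
    if n_symbolic:
        logger.info("%s: skipped %d symbolic/breakend ALT alleles", path, n_symbolic)
    return records


def assemble_cohort(
    file_manifest: Sequence[tuple[str | Path, str, str]],
    pass_only: bool = True,
) -> Cohort:
    """Build a :class:`Cohort` from (path, group, sample) entries.

    Sample order within each group follows manifest order; duplicate sample
    labels are a configuration error.
    """
    if not file_manifest:
        raise ConfigError("empty file manifest")
    cohort = Cohort()
    for path, group, sample in file_manifest:
        if sample in cohort.variants:
            raise ConfigError(f"duplicate sample label {sample!r} in manifest")
        cohort.groups.setdefault(group, []).append(sample)
        cohort.variants[sample] = read_vcf(path, sample_label=sample, pass_only=pass_only)
    cohort.validate()
    return cohort


def write_vcf(records: Iterable[VariantRecord], path: str | Path,
              contigs: dict[str, int] | None = None) -> None:
    """Write records as a minimal site-only VCF v4.2 (sorted by chrom, pos)."""
    recs = sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    lines = ["##fileformat=VCFv4.2"]
    if contigs:
        lines += [f"##contig=<ID={c},length={l}>" for c, l in contigs.items()]
    else:
        lines += [f"##contig=<ID={c}>" for c in dict.fromkeys(r.chrom for r in recs)]
    lines.append('##FILTER=<ID=PASS,Description="All filters passed">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for r in recs:
        info = ";".join(f"{k}={v}" for k, v in r.info.items()) or "."
        flt = "PASS" if r.filter_pass else "fail"
        lines.append(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\t{flt}\t{info}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_variants_tsv(cohort: Cohort, path: str | Path) -> None:
    """Long-format TSV dump: sample, group, chrom, pos, ref, alt, class, indel_len."""
    header = "sample\tgroup\tchrom\tpos\tref\talt\tclass\tindel_len"
    out = [header]
    for group, members in cohort.groups.items():
        for sample in members:
            for r in cohort.variants[sample]:
                out.append(
                    f"{sample}\t{group}\t{r.chrom}\t{r.pos}\t{r.ref}\t{r.alt}"
                    f"\t{r.vclass.value}\t{r.indel_len}"
                )
    Path(path).write_text("\n".join(out) + "\n")
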