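"""Readers and writers for the external formats the pipeline touches.

Supported formats:

* a VCFv4.2 subset (``CHROM/POS/ID/REF/ALT/QUAL/FILTER/INFO/FORMAT`` with a
  ``GT`` subfield; other FORMAT subfields ignored; plain text, bgzip not
  required),
* PLINK-style 6/7-column PED pedigree files,
* tab-separated annotation tables (per-variant consequence class, per-database
  minor allele frequencies, per-tool deleteriousness calls, QC metrics),
* tab-separated per-gene reference-population count tables,
* the pipeline's own audit-trace and results-report TSVs, and
* the run configuration (JSON).

Coordinates are 1-based fully closed, as in VCF.  Multiallelic records are
split on read into one :class:`VariantKey` per alternate allele.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "VariantKey",
    "VariantAnnotation",
    "CohortGenotypes",
    "ReferenceCounts",
    "RunConfig",
    "FormatError",
    "MISSING",
    "CONSEQUENCES",
    "FUNCTIONAL_CONSEQUENCES",
    "read_vcf",
    "write_vcf",
    "read_ped",
    "read_annotations",
    "read_reference_counts",
    "write_reference_counts",
    "write_filter_trace",
    "read_filter_trace",
    "write_report",
    "read_report",
]

#: Sentinel genotype code for a missing call (``./.`` or an unresolvable
#: other-alt genotype after multiallelic splitting).
MISSING: int = -1

CONSEQUENCES = ("missense", "nonsense", "frameshift", "splice_site", "synonymous", "other")
FUNCTIONAL_CONSEQUENCES = frozenset({"missense", "nonsense", "frameshift", "splice_site"})


class FormatError(ValueError):
    """Raised when an input file violates the supported dialect."""


class VariantKey(NamedTuple):
    """One normalized biallelic variant site (chrom, 1-based pos, ref, alt)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    @classmethod
    def parse(cls, text: str) -> "VariantKey":
        """Parse ``chrom:pos:ref>alt`` (or ``chrom:pos:ref:alt``)."""
        parts = text.replace(">", ":").split(":")
        if len(parts) != 4:
            raise FormatError(f"cannot parse variant key {text!r}")
        chrom, pos, ref, alt = parts
        return cls(chrom, int(pos), ref.upper(), alt.upper())


@dataclass
class VariantAnnotation:
    """Per-variant annotations consumed by the filter cascade.

    ``maf_by_db`` maps database name -> MAF in [0, 1]; a database absent from
    the mapping means the variant is not reported there (distinct from a MAF
    of 0.0).  ``tool_calls`` maps prediction-tool name -> ``deleterious`` /
    ``tolerated`` / ``missing``.
    """

    key: VariantKey
    gene: str
    consequence: str
    maf_by_db: dict[str, float] = field(default_factory=dict)
    tool_calls: dict[str, str] = field(default_factory=dict)
    qc: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.gene:
            raise FormatError(f"variant {self.key} has an empty gene symbol")
        if self.consequence not in CONSEQUENCES:
            raise FormatError(
                f"variant {self.key}: unknown consequence {self.consequence!r}"
            )
        for db, maf in self.maf_by_db.items():
            if not (0.0 <= maf <= 1.0):
                raise FormatError(
                    f"variant {self.key}: MAF {maf!r} in {db} outside [0, 1]"
                )
        cr = self.qc.get("call_rate")
        if cr is not None and not (0.0 <= cr <= 1.0):
            raise FormatError(f"variant {self.key}: call_rate {cr!r} outside [0, 1]")


@dataclass
class CohortGenotypes:
    """Genotype calls for every (variant, sample) pair in the cohort.

    ``calls[key]`` is an ``int8`` array aligned with ``sample_ids`` holding
    alt-allele dosages 0/1/2 or :data:`MISSING`.
    """

    sample_ids: list[str]
    calls: dict[VariantKey, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {s: i for i, s in enumerate(self.sample_ids)}
        if len(self._index) != len(self.sample_ids):
            raise FormatError("duplicate sample ids in cohort")

    def sample_index(self, sample_id: str) -> int:
        return self._index[sample_id]

    def dosage(self, key: VariantKey, sample_id: str) -> int:
        """Alt-allele dosage for one sample, or MISSING."""
        return int(self.calls[key][self._index[sample_id]])

    def carriers(self, key: VariantKey) -> list[str]:
        """Sample ids carrying at least one alt allele."""
        arr = self.calls[key]
        return [self.sample_ids[i] for i in np.flatnonzero(arr > 0)]

    def matrix(self, keys: list[VariantKey]) -> np.ndarray:
        """Stack calls for ``keys`` into an (n_keys, n_samples) array."""
        if not keys:
            return np.zeros((0, len(self.sample_ids)), dtype=np.int8)
        return np.stack([self.calls[k] for k in keys])


@dataclass
class ReferenceCounts:
    """Per-gene qualifying-variant counts in the reference population.

    Either the allele-level pair (``ref_alt_alleles`` / ``ref_total_alleles``)
    or the carrier-level pair (``ref_carriers`` / ``ref_total_individuals``)
    may be absent, but at least one pair must be present.
    """

    gene: str
    ref_alt_alleles: int | None = None
    ref_total_alleles: int | None = None
    ref_carriers: int | None = None
    ref_total_individuals: int | None = None

    def __post_init__(self) -> None:
        has_alleles = self.ref_alt_alleles is not None and self.ref_total_alleles is not None
        has_carriers = self.ref_carriers is not None and self.ref_total_individuals is not None
        if not (has_alleles or has_carriers):
            raise FormatError(f"gene {self.gene}: no complete reference count pair")
        if has_alleles and not (0 <= self.ref_alt_alleles <= self.ref_total_alleles):
            raise FormatError(f"gene {self.gene}: allele counts inconsistent")
        if has_carriers and not (0 <= self.ref_carriers <= self.ref_total_individuals):
            raise FormatError(f"gene {self.gene}: carrier counts inconsistent")


@dataclass
class RunConfig:
    """All tunable thresholds of a pipeline run.

    Defaults reproduce the published filter cascade: MAF < 2.5% aggregated as
    a maximum across databases, variants present in more than 1 unaffected
    control excluded, genes with qualifying variants in more than 1 proband
    retained, and a 3-of-5 deleteriousness consensus reported as an
    annotation (set ``consensus_removes`` to make it a removing filter).
    """

    maf_threshold: float = 0.025
    maf_aggregation: str = "max_across_dbs"  # or "all_dbs"
    consequence_whitelist: frozenset[str] = frozenset(FUNCTIONAL_CONSEQUENCES)
    qc_thresholds: dict[str, float] = field(default_factory=dict)
    max_unaffected_controls_with_variant: int = 1
    min_probands_per_gene: int = 2
    consensus_k: int = 3
    consensus_n: int = 5
    consensus_removes: bool = False
    gene_whitelist: frozenset[str] | None = None
    segregation_mode: str = "strict"  # or "allow_nonpenetrance"
    burden_unit: str = "carriers"  # or "alleles"
    test_sidedness: str = "enrichment"  # or "two_sided"
    mtc_method: str = "bonferroni"  # or "benjamini_hochberg" / "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.maf_threshold <= 1.0):
            raise ValueError("maf_threshold must be in (0, 1]")
        if self.maf_aggregation not in ("max_across_dbs", "all_dbs"):
            raise ValueError(f"unknown maf_aggregation {self.maf_aggregation!r}")
        if self.consensus_k > self.consensus_n or self.consensus_k < 1:
            raise ValueError("consensus requires 1 <= k <= n")
        if self.max_unaffected_controls_with_variant < 0:
            raise ValueError("max_unaffected_controls_with_variant must be >= 0")
        if self.min_probands_per_gene < 1:
            raise ValueError("min_probands_per_gene must be >= 1")
        if self.segregation_mode not in ("strict", "allow_nonpenetrance"):
            raise ValueError(f"unknown segregation_mode {self.segregation_mode!r}")
        if self.burden_unit not in ("carriers", "alleles"):
            raise ValueError(f"unknown burden_unit {self.burden_unit!r}")
        if self.test_sidedness not in ("enrichment", "two_sided"):
            raise ValueError(f"unknown test_sidedness {self.test_sidedness!r}")
        if self.mtc_method not in ("bonferroni", "benjamini_hochberg", "none"):
            raise ValueError(f"unknown mtc_method {self.mtc_method!r}")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        self.consequence_whitelist = frozenset(self.consequence_whitelist)
        if self.gene_whitelist is not None:
            self.gene_whitelist = frozenset(self.gene_whitelist)

    def to_json(self, path: str | Path | None = None) -> str:
        d = dataclasses.asdict(self)
        d["consequence_whitelist"] = sorted(self.consequence_whitelist)
        d["gene_whitelist"] = (
            None if self.gene_whitelist is None else sorted(self.gene_whitelist)
        )
        text = json.dumps(d, indent=2, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RunConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        if d.get("consequence_whitelist") is not None:
            d["consequence_whitelist"] = frozenset(d["consequence_whitelist"])
        if d.get("gene_whitelist") is not None:
            d["gene_whitelist"] = frozenset(d["gene_whitelist"])
        return cls(**d)


# ---------------------------------------------------------------------------
# VCF


def _validate_vcf_header(path: Path) -> None:
    """Light pre-scan of the header so malformed files fail with a line number."""
    with open(path) as fh:
        lineno = 0
        for line in fh:
            lineno += 1
            if lineno == 1 and not line.startswith("##fileformat=VCF"):
                raise FormatError(f"{path}:1: missing ##fileformat header line")
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.rstrip("\n").split("\t")
                if len(cols) < 10:
                    raise FormatError(
                        f"{path}:{lineno}: VCF needs FORMAT and >=1 sample column"
                    )
                return
            raise FormatError(f"{path}:{lineno}: expected #CHROM header line")
    raise FormatError(f"{path}: no #CHROM header line found")


def _split_genotypes(gts: list[list[int]], alt_index: int, n_alts: int) -> np.ndarray:
    """Recode raw allele-index genotypes against one split alternate allele.

    A genotype containing allele ``alt_index`` becomes het/homalt for that
    split key; a genotype made of reference alleles only is homref; a
    genotype whose only non-reference alleles are *other* alternates is
    recoded to missing (splitting must not fabricate reference calls).
    """
    out = np.empty(len(gts), dtype=np.int8)
    for i, g in enumerate(gts):
        alleles = g[:-1]  # last element is the phased flag
        if any(a < 0 for a in alleles):
            out[i] = MISSING
            continue
        dosage = sum(1 for a in alleles if a == alt_index)
        if dosage > 0:
            out[i] = dosage
        elif all(a == 0 for a in alleles):
            out[i] = 0
        else:
            out[i] = MISSING
    return out


def read_vcf(path: str | Path) -> tuple[list[VariantKey], CohortGenotypes]:
    """Read a VCF, splitting multiallelic records into per-alt keys.

    Returns keys in input order (a multiallelic record contributes one key
    per alternate allele, in ALT order) and genotype dosages recoded against
    each split allele.  Unphased and phased separators are both accepted;
    missing alleles map to missing calls.
    """
    path = Path(path)
    _validate_vcf_header(path)
    vcf = VCF(str(path))
    genotypes = CohortGenotypes(sample_ids=list(vcf.samples))
    keys: list[VariantKey] = []
    for record in vcf:
        if "GT" not in (record.FORMAT or []):
            raise FormatError(
                f"{path}: record {record.CHROM}:{record.POS} has no GT subfield"
            )
        gts = record.genotypes
        alts = record.ALT
        for j, alt in enumerate(alts, start=1):
            key = VariantKey(record.CHROM, record.POS, record.REF, alt)
            keys.append(key)
            genotypes.calls[key] = _split_genotypes(gts, j, len(alts))
    return keys, genotypes


_GT_STRINGS = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(
    keys: list[VariantKey],
    genotypes: CohortGenotypes,
    path: str | Path,
) -> None:
    """Write biallelic records (one per key, input order) in the VCF dialect."""
    path = Path(path)
    contigs = []
    for k in keys:
        if k.chrom not in contigs:
            contigs.append(k.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=famburden\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.sample_ids)
            + "\n"
        )
        for key in keys:
            gt_field = "\t".join(_GT_STRINGS[int(g)] for g in genotypes.calls[key])
            fh.write(
                f"{key.chrom}\t{key.pos}\t.\t{key.ref}\t{key.alt}\t.\tPASS\t.\tGT\t{gt_field}\n"
            )


# ---------------------------------------------------------------------------
# PED

_PHENOTYPE_CODES = {"1": "unaffected", "2": "affected", "0": "unknown", "-9": "unknown"}
_SEX_CODES = {"1": "male", "2": "female", "0": "unknown"}


def read_ped(path: str | Path) -> pd.DataFrame:
    """Read a PLINK-style PED file into a tidy pedigree table.

    Columns: ``family_id, individual_id, father_id, mother_id, sex, status,
    is_proband``.  Phenotype codes 1/2/0/-9 map to unaffected/affected/
    unknown; a ``0`` parent id marks a founder.  An optional 7th column with
    value 1 flags the proband; without it, the first affected member of each
    family (file order) is taken as the proband.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: PED needs >=6 columns")
            fam, ind, father, mother, sex, pheno = fields[:6]
            if ind in (father, mother):
                raise FormatError(
                    f"{path}:{lineno}: individual {ind} listed as its own parent"
                )
            if pheno not in _PHENOTYPE_CODES:
                raise FormatError(f"{path}:{lineno}: unknown phenotype code {pheno!r}")
            if sex not in _SEX_CODES:
                raise FormatError(f"{path}:{lineno}: unknown sex code {sex!r}")
            proband = len(fields) >= 7 and fields[6] == "1"
            rows.append(
                (fam, ind, father, mother, _SEX_CODES[sex], _PHENOTYPE_CODES[pheno], proband)
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "family_id",
            "individual_id",
            "father_id",
            "mother_id",
            "sex",
            "status",
            "is_proband",
        ],
    )
    dup = df.duplicated(subset=["family_id", "individual_id"])
    if dup.any():
        first = df[dup].iloc[0]
        raise FormatError(
            f"{path}: duplicate individual {first.individual_id} in family {first.family_id}"
        )
    # default proband: first affected member per family when no flag was given
    for fam, group in df.groupby("family_id", sort=False):
        if not group["is_proband"].any():
            affected = group.index[group["status"] == "affected"]
            if len(affected):
                df.loc[affected[0], "is_proband"] = True
    return df


# ---------------------------------------------------------------------------
# Annotation TSV

_QC_FIELDS = ("site_quality", "mean_depth", "call_rate")
_TOOL_CALLS = {
    "D": "deleterious",
    "deleterious": "deleterious",
    "T": "tolerated",
    "tolerated": "tolerated",
}


def _is_absent(cell) -> bool:
    return cell is None or (isinstance(cell, float) and math.isnan(cell)) or cell in ("", ".")


def read_annotations(
    path: str | Path,
    known_keys: set[VariantKey] | None = None,
) -> list[VariantAnnotation]:
    """Read the annotation TSV.

    MAF columns are named ``maf_<database>``, tool columns ``tool_<name>``,
    QC columns ``site_quality``/``mean_depth``/``call_rate``.  Empty cells
    (or ``.``) mean *absent* — for a MAF this is distinct from 0.0.  Rows
    whose key is absent from ``known_keys`` (when given) are kept with a
    warning on stderr.
    """
    import sys

    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt", "gene", "consequence"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    maf_cols = [c for c in df.columns if c.startswith("maf_")]
    tool_cols = [c for c in df.columns if c.startswith("tool_")]
    annotations = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        key = VariantKey(str(d["chrom"]), int(d["pos"]), d["ref"], d["alt"])
        if known_keys is not None and key not in known_keys:
            print(f"warning: annotation row for unknown variant {key}", file=sys.stderr)
        maf_by_db = {}
        for col in maf_cols:
            if not _is_absent(d[col]):
                maf_by_db[col[len("maf_"):]] = float(d[col])
        tool_calls = {}
        for col in tool_cols:
            cell = d[col]
            if _is_absent(cell):
                tool_calls[col[len("tool_"):]] = "missing"
            else:
                call = _TOOL_CALLS.get(str(cell))
                if call is None:
                    raise FormatError(f"{path}: unknown tool call {cell!r} for {key}")
                tool_calls[col[len("tool_"):]] = call
        qc = {f: float(d[f]) for f in _QC_FIELDS if f in d and not _is_absent(d[f])}
        annotations.append(
            VariantAnnotation(
                key=key,
                gene=str(d["gene"]),
                consequence=str(d["consequence"]),
                maf_by_db=maf_by_db,
                tool_calls=tool_calls,
                qc=qc,
            )
        )
    return annotations


def write_annotations(annotations: list[VariantAnnotation], path: str | Path) -> None:
    """Write the annotation TSV (inverse of :func:`read_annotations`)."""
    dbs = sorted({db for a in annotations for db in a.maf_by_db})
    tools = sorted({t for a in annotations for t in a.tool_calls})
    qc_fields = [f for f in _QC_FIELDS if any(f in a.qc for a in annotations)]
    cols = ["chrom", "pos", "ref", "alt", "gene", "consequence"]
    cols += [f"maf_{db}" for db in dbs] + [f"tool_{t}" for t in tools] + qc_fields
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for a in annotations:
            row = [a.key.chrom, str(a.key.pos), a.key.ref, a.key.alt, a.gene, a.consequence]
            for db in dbs:
                v = a.maf_by_db.get(db)
                row.append("." if v is None else format(v, ".6g"))
            for t in tools:
                call = a.tool_calls.get(t, "missing")
                row.append({"deleterious": "D", "tolerated": "T", "missing": "."}[call])
            for f in qc_fields:
                v = a.qc.get(f)
                row.append("." if v is None else format(v, ".6g"))
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Reference counts TSV


def read_reference_counts(path: str | Path) -> dict[str, ReferenceCounts]:
    """Read the per-gene reference-population count table."""
    df = pd.read_csv(path, sep="\t")
    if "gene" not in df.columns:
        raise FormatError(f"{path}: missing 'gene' column")
    out: dict[str, ReferenceCounts] = {}
    int_cols = ("ref_alt_alleles", "ref_total_alleles", "ref_carriers", "ref_total_individuals")
    for row in df.itertuples(index=False):
        d = row._asdict()
        kwargs = {}
        for c in int_cols:
            if c in d and not _is_absent(d[c]):
                kwargs[c] = int(d[c])
        gene = str(d["gene"])
        if gene in out:
            raise FormatError(f"{path}: duplicate gene {gene}")
        out[gene] = ReferenceCounts(gene=gene, **kwargs)
    return out


def write_reference_counts(counts: dict[str, ReferenceCounts], path: str | Path) -> None:
    cols = ["gene", "ref_alt_alleles", "ref_total_alleles", "ref_carriers", "ref_total_individuals"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for gene in sorted(counts):
            rc = counts[gene]
            row = [gene] + [
                "." if getattr(rc, c) is None else str(getattr(rc, c)) for c in cols[1:]
            ]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Trace and report TSVs (round-trippable)

_TRACE_COLS = ("chrom", "pos", "ref", "alt", "gene", "disposition", "removed_by", "details")


def write_filter_trace(traces: list, path: str | Path, seed: int | None = None) -> None:
    """Write the per-variant audit trace; round-trips field-for-field."""
    if not traces:
        raise ValueError("no trace records to write")
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        fh.write("\t".join(_TRACE_COLS) + "\n")
        for t in traces:
            fh.write(
                "\t".join(
                    [
                        t.key.chrom,
                        str(t.key.pos),
                        t.key.ref,
                        t.key.alt,
                        t.gene,
                        t.disposition,
                        t.removed_by or ".",
                        t.details or ".",
                    ]
                )
                + "\n"
            )


def read_filter_trace(path: str | Path) -> list:
    from .filters import FilterTrace  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str}, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.append(
            FilterTrace(
                key=VariantKey(str(d["chrom"]), int(d["pos"]), d["ref"], d["alt"]),
                gene=d["gene"],
                disposition=d["disposition"],
                removed_by=None if d["removed_by"] == "." else d["removed_by"],
                details=None if d["details"] == "." else str(d["details"]),
            )
        )
    return out


_REPORT_COLS = (
    "rank",
    "gene",
    "cohort_alt",
    "cohort_total",
    "ref_alt",
    "ref_total",
    "odds_ratio",
    "p_value",
    "p_adjusted",
    "n_segregating_families",
)


def _format_or(x: float) -> str:
    if math.isnan(x):
        return "undefined"
    if math.isinf(x):
        return "inf"
    return format(x, ".6g")


def write_report(results: list, path: str | Path, seed: int | None = None) -> None:
    """Write the gene-burden report, sorted by adjusted p (ties: gene symbol)."""
    if not results:
        raise ValueError("no burden results to write")
    ordered = sorted(results, key=lambda r: (r.p_adjusted, r.gene))
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        fh.write("\t".join(_REPORT_COLS) + "\n")
        for r in ordered:
            fh.write(
                "\t".join(
                    [
                        str(r.rank),
                        r.gene,
                        str(r.cohort_alt),
                        str(r.cohort_total),
                        str(r.ref_alt),
                        str(r.ref_total),
                        _format_or(r.odds_ratio),
                        format(r.p_value, ".6g"),
                        format(r.p_adjusted, ".6g"),
                        str(r.n_segregating_families),
                    ]
                )
                + "\n"
            )


def read_report(path: str | Path) -> list:
    from .burden import GeneBurdenResult

    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        orv = d["odds_ratio"]
        if orv == "undefined":
            orv = math.nan
        out.append(
            GeneBurdenResult(
                gene=d["gene"],
                cohort_alt=int(d["cohort_alt"]),
                cohort_total=int(d["cohort_total"]),
                ref_alt=int(d["ref_alt"]),
                ref_total=int(d["ref_total"]),
                odds_ratio=float(orv),
                p_value=float(d["p_value"]),
                p_adjusted=float(d["p_adjusted"]),
                rank=int(d["rank"]),
                n_segregating_families=int(d["n_segregating_families"]),
            )
        )
    return out
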