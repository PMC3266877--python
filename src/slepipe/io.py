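"""Readers, writers, run configuration and the packaged known-locus table.

Coordinate conventions: VCF and all TSV interchange are 1-based; BED probe
annotations are 0-based half-open, converted only at this boundary.  The
genotype TSV dialect is samples as rows, SNPs as columns, values in
{0,1,2,NA} counting copies of allele 1.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import (
    CASE,
    CONTROL,
    MISSING,
    GenotypeMatrix,
    ExpressionMatrix,
    ProbeAnnotation,
    SlepipeError,
    ConfigurationError,
)

__all__ = [
    "KnownLocusRecord",
    "RunConfig",
    "read_genotypes",
    "write_genotypes_vcf",
    "write_genotypes_tsv",
    "read_phenotypes_tsv",
    "write_phenotypes_tsv",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_probe_bed",
    "write_probe_bed",
    "load_known_loci",
    "load_table_fixture",
    "write_report",
]

#: SHA-256 of the packaged known-locus table; guards accidental edits.
_KNOWN_LOCI_SHA256 = (
    "7aa7df515751fcde4bc4e551afcdc567e1869373bb88ec821923be5e9f7ceb02")


@dataclass(frozen=True)
class KnownLocusRecord:
    """One previously reported susceptibility locus."""

    snp_id: str
    chrom: int
    pos: int
    gene_label: str
    p_reported: float
    eqtl_positive: bool
    discovered_in: frozenset[str]

    def __post_init__(self) -> None:
        if not self.discovered_in:
            raise ValueError("discovered_in must be nonempty")
        if not (0.0 < self.p_reported <= 1.0):
            raise ValueError("p_reported must be in (0, 1]")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Read genotypes from VCF or genotype TSV.

    Multi-allelic VCF records are rejected and counted (the count is
    attached as ``matrix.n_rejected_multiallelic``); dosage counts copies
    of the single ALT allele.  Format is inferred from the suffix when not
    given.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix in {".vcf", ".gz", ".bcf"} else "tsv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_genotype_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rows, meta = [], []
    n_multi = 0
    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        gts = rec.genotype.array()
        if gts.shape[1] > 3:
            raise SlepipeError(
                f"mixed-ploidy record at line for {rec.ID or rec.POS}")
        alleles = gts[:, :2]
        if np.any(alleles > 1):
            raise SlepipeError(
                f"unexpected allele index in record {rec.ID or rec.POS}")
        dose = np.where((alleles < 0).any(axis=1), MISSING,
                        alleles.clip(min=0).sum(axis=1))
        rows.append(dose.astype(np.int8))
        meta.append((rec.ID or f"{rec.CHROM}:{rec.POS}",
                     int(str(rec.CHROM).removeprefix("chr")), rec.POS,
                     rec.ALT[0], rec.REF))
    g = np.stack(rows, axis=1) if rows else np.empty((len(sample_ids), 0), np.int8)
    snps = pd.DataFrame(meta, columns=["snp_id", "chrom", "pos",
                                       "allele1", "allele2"])
    samples = pd.DataFrame({"sample_id": sample_ids, "status": CONTROL,
                            "stage": "unassigned"})
    gm = GenotypeMatrix(g, snps, samples)
    gm.n_rejected_multiallelic = n_multi  # type: ignore[attr-defined]
    return gm


def _read_genotype_tsv(path: Path) -> GenotypeMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    g = frame.to_numpy(dtype=float)
    g = np.where(np.isnan(g), MISSING, g).astype(np.int8)
    snps = pd.DataFrame(
        {"snp_id": frame.columns, "chrom": 1,
         "pos": np.arange(1, len(frame.columns) + 1),
         "allele1": "A", "allele2": "G"})
    samples = pd.DataFrame({"sample_id": frame.index.astype(str),
                            "status": CONTROL, "stage": "unassigned"})
    return GenotypeMatrix(g, snps, samples)


def write_genotypes_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal single-ALT VCF (GT fields only, 1-based positions)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=slepipe\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in sorted(genotypes.snps["chrom"].unique()):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.samples["sample_id"]) + "\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        order = genotypes.snps.sort_values(["chrom", "pos"]).index
        for j in order:
            row = genotypes.snps.iloc[j]
            calls = "\t".join(gt_map[int(v)] for v in genotypes.genotypes[:, j])
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['snp_id']}\t"
                     f"{row['allele2']}\t{row['allele1']}\t.\tPASS\t.\tGT\t"
                     f"{calls}\n")


def write_genotypes_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    frame = pd.DataFrame(
        genotypes.genotypes.astype(float),
        index=genotypes.samples["sample_id"],
        columns=genotypes.snps["snp_id"])
    frame = frame.replace(float(MISSING), np.nan)
    frame.index.name = "sample_id"
    frame.to_csv(path, sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# phenotypes, expression, probes
# ---------------------------------------------------------------------------

def write_phenotypes_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    genotypes.samples[["sample_id", "status", "stage"]].to_csv(
        path, sep="\t", index=False)


def read_phenotypes_tsv(path: str | Path) -> pd.DataFrame:
    pheno = pd.read_csv(path, sep="\t")
    bad = ~pheno["status"].isin([CONTROL, CASE])
    if bad.any():
        raise SlepipeError("phenotype status must be 1 (control) or 2 (case)")
    return pheno


def write_expression_tsv(expression: ExpressionMatrix, path: str | Path) -> None:
    expression.values.to_csv(path, sep="\t")


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    return ExpressionMatrix(pd.read_csv(path, sep="\t", index_col=0))


def write_probe_bed(probes: ProbeAnnotation, path: str | Path) -> None:
    probes.table[["chrom", "start", "end", "probe_id", "gene_label"]].to_csv(
        path, sep="\t", index=False, header=False)


def read_probe_bed(path: str | Path) -> ProbeAnnotation:
    tab = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "probe_id", "gene_label"])
    return ProbeAnnotation(
        tab[["probe_id", "chrom", "start", "end", "gene_label"]])


# ---------------------------------------------------------------------------
# known loci fixture
# ---------------------------------------------------------------------------

def load_known_loci() -> pd.DataFrame:
    """The packaged table of 26 previously reported susceptibility loci.

    Columns include the reported discovery-stage P-value, the cis-eQTL
    positivity flag, and the population (caucasian/asian) in which the
    locus was first reported.  The file checksum is verified on load.
    """
    res = importlib.resources.files("slepipe").joinpath(
        "data/known_sle_loci.tsv")
    raw = res.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _KNOWN_LOCI_SHA256:
        raise SlepipeError("known-locus table checksum mismatch")
    from io import BytesIO

    tab = pd.read_csv(BytesIO(raw), sep="\t")
    tab["eqtl_positive"] = tab["eqtl_positive"].astype(bool)
    return tab


def load_table_fixture() -> list[KnownLocusRecord]:
    """The known-locus table as typed records."""
    tab = load_known_loci()
    return [
        KnownLocusRecord(
            snp_id=row.snp_id, chrom=int(row.chrom), pos=int(row.pos),
            gene_label=row.gene_label, p_reported=float(row.p_reported),
            eqtl_positive=bool(row.eqtl_positive),
            discovered_in=frozenset(str(row.discovered_in).split(",")),
        )
        for row in tab.itertuples()
    ]


# ---------------------------------------------------------------------------
# run configuration and reports
# ---------------------------------------------------------------------------

_CONFIG_FIELDS = {
    "seed", "simulation", "qc_thresholds", "selection_thresholds",
    "eqtl_window_bp", "eqtl_q_threshold", "paths", "report",
}


@dataclass
class RunConfig:
    """Serializable run configuration: thresholds, paths and the seed."""

    seed: int = 0
    simulation: dict = field(default_factory=dict)
    qc_thresholds: dict = field(default_factory=dict)
    selection_thresholds: dict = field(default_factory=dict)
    eqtl_window_bp: int = 300_000
    eqtl_q_threshold: float = 0.2
    paths: dict = field(default_factory=dict)
    report: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - _CONFIG_FIELDS
        if unknown:
            raise ConfigurationError(
                f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()


def write_report(
    outdir: str | Path,
    config: RunConfig,
    stage_outputs: dict[str, pd.DataFrame],
) -> Path:
    """Write per-stage TSVs plus a manifest enabling exact re-runs.

    Each TSV carries a header comment naming the producing stage and the
    config hash; the manifest records the seed, config hash and per-stage
    row counts.  Missing expected stages are noted, not silently dropped.
    """
    if not stage_outputs:
        raise SlepipeError("write_report needs at least one stage output")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    counts = {}
    for stage, frame in stage_outputs.items():
        p = outdir / f"{stage}.tsv"
        with open(p, "w") as fh:
            fh.write(f"# producer=slepipe.{stage} config_hash={chash}\n")
            frame.to_csv(fh, sep="\t", index=False)
        counts[stage] = int(len(frame))
    expected = {"gwas", "eqtl", "decisions"}
    manifest = {
        "config_hash": chash,
        "seed": config.seed,
        "stage_row_counts": counts,
        "missing_stages": sorted(expected - set(stage_outputs)),
    }
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()).hexdigest()
    mpath = outdir / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return mpath
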