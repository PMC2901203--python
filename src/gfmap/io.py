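"""File formats and run configuration.

Primary interchange is tab-separated text:

* haplotypes file — one row per individual: ``id``, maternal haplotype
  string, paternal haplotype string (alleles 0/1, phased);
* marker map file — ``marker`` id, ``position_cM``;
* phenotype file — ``id``, ``phenotype``.

A minimal VCF (phased GT only) can be exported for interoperability.  The
declarative run configuration is YAML, schema-validated with unknown keys
rejected, and every CLI run writes a JSON manifest recording the config,
master seed and package versions so outputs can be replayed exactly.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .ld_simulator import DemographyConfig, StudyData

__all__ = [
    "StudyFormatError",
    "write_study",
    "read_study",
    "write_vcf",
    "read_vcf",
    "RunConfig",
    "load_config",
    "write_manifest",
]


class StudyFormatError(ValueError):
    """Malformed study file; the message names the offending line."""


# ---------------------------------------------------------------------------
# Tabular study files
# ---------------------------------------------------------------------------


def write_study(study: StudyData, out_dir, ids=None) -> dict:
    """Write haplotypes/markers/phenotypes TSV files; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n = study.n_individuals
    ids = list(ids) if ids is not None else [f"ind{i}" for i in range(n)]

    hap_path = out_dir / "haplotypes.tsv"
    with open(hap_path, "w") as fh:
        fh.write("id\tmaternal\tpaternal\n")
        for i in range(n):
            m = "".join(map(str, study.maternal_haplotypes[i]))
            p = "".join(map(str, study.paternal_haplotypes[i]))
            fh.write(f"{ids[i]}\t{m}\t{p}\n")

    map_path = out_dir / "markers.tsv"
    pd.DataFrame(
        {
            "marker": [f"m{j}" for j in range(study.n_markers)],
            "position_cM": study.positions_cM,
        }
    ).to_csv(map_path, sep="\t", index=False)

    paths = {"haplotypes": hap_path, "markers": map_path}
    if study.y is not None:
        phe_path = out_dir / "phenotypes.tsv"
        pd.DataFrame({"id": ids, "phenotype": study.y}).to_csv(
            phe_path, sep="\t", index=False
        )
        paths["phenotypes"] = phe_path
    return paths


def _parse_hap(s: str, n_markers: int, line_no: int, path) -> np.ndarray:
    if len(s) != n_markers:
        raise StudyFormatError(
            f"{path}, line {line_no}: haplotype string of length {len(s)}, "
            f"expected {n_markers} markers"
        )
    arr = np.frombuffer(s.encode(), dtype=np.uint8) - ord("0")
    if arr.max(initial=0) > 1:
        raise StudyFormatError(
            f"{path}, line {line_no}: allele codes must be 0 or 1"
        )
    return arr


def read_study(haplotype_file, map_file, phenotype_file=None) -> StudyData:
    """Read phased study data back from the tabular files.

    Raises :class:`StudyFormatError` with the file and line number on
    inconsistent dimensions, non-binary allele codes or non-numeric
    phenotypes.
    """
    marker_map = pd.read_csv(map_file, sep="\t")
    if not {"marker", "position_cM"} <= set(marker_map.columns):
        raise StudyFormatError(f"{map_file}: need columns marker, position_cM")
    positions = marker_map["position_cM"].to_numpy(dtype=float)
    n_markers = len(positions)

    ids, mats, pats = [], [], []
    with open(haplotype_file) as fh:
        header = fh.readline()
        if header.split() != ["id", "maternal", "paternal"]:
            raise StudyFormatError(
                f"{haplotype_file}, line 1: expected header 'id maternal paternal'"
            )
        for line_no, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 3:
                raise StudyFormatError(
                    f"{haplotype_file}, line {line_no}: expected 3 columns"
                )
            ids.append(parts[0])
            mats.append(_parse_hap(parts[1], n_markers, line_no, haplotype_file))
            pats.append(_parse_hap(parts[2], n_markers, line_no, haplotype_file))

    y = None
    if phenotype_file is not None:
        phe = pd.read_csv(phenotype_file, sep="\t", dtype={"id": str})
        if not {"id", "phenotype"} <= set(phe.columns):
            raise StudyFormatError(f"{phenotype_file}: need columns id, phenotype")
        lookup = dict(zip(phe["id"], phe["phenotype"]))
        y = np.empty(len(ids))
        for i, ind in enumerate(ids):
            if ind not in lookup:
                raise StudyFormatError(f"{phenotype_file}: no phenotype for id {ind}")
            try:
                y[i] = float(lookup[ind])
            except (TypeError, ValueError) as err:
                raise StudyFormatError(
                    f"{phenotype_file}: non-numeric phenotype for id {ind}"
                ) from err

    return StudyData(
        maternal_haplotypes=np.array(mats, dtype=np.uint8),
        paternal_haplotypes=np.array(pats, dtype=np.uint8),
        positions_cM=positions,
        y=y,
    )


# ---------------------------------------------------------------------------
# Minimal VCF export / import
# ---------------------------------------------------------------------------

#: base pairs per cM used to place markers on an integer coordinate axis
_BP_PER_CM = 100_000


def write_vcf(study: StudyData, path, ids=None) -> Path:
    """Export window genotypes as a minimal VCF with phased GT fields."""
    path = Path(path)
    n = study.n_individuals
    ids = list(ids) if ids is not None else [f"ind{i}" for i in range(n)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=gfmap\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(ids)
            + "\n"
        )
        for j in range(study.n_markers):
            pos_bp = int(round(study.positions_cM[j] * _BP_PER_CM)) + 1
            gts = "\t".join(
                f"{study.maternal_haplotypes[i, j]}|{study.paternal_haplotypes[i, j]}"
                for i in range(n)
            )
            fh.write(f"1\t{pos_bp}\tm{j}\tA\tC\t.\t.\t.\tGT\t{gts}\n")
    return path


def read_vcf(path) -> StudyData:
    """Re-import a minimal VCF written by :func:`write_vcf` (phased GT)."""
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        mats, pats, positions = [], [], []
        for rec in vf:
            positions.append((rec.pos - 1) / _BP_PER_CM)
            m_row, p_row = [], []
            for s in samples:
                gt = rec.samples[s]["GT"]
                if len(gt) != 2 or not rec.samples[s].phased:
                    raise StudyFormatError(
                        f"{path}: unphased or non-diploid GT at {rec.id}"
                    )
                m_row.append(gt[0])
                p_row.append(gt[1])
            mats.append(m_row)
            pats.append(p_row)
    return StudyData(
        maternal_haplotypes=np.array(mats, dtype=np.uint8).T,
        paternal_haplotypes=np.array(pats, dtype=np.uint8).T,
        positions_cM=np.array(positions, dtype=float),
    )


# ---------------------------------------------------------------------------
# Declarative run configuration
# ---------------------------------------------------------------------------


class DemographySection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    phase1_size: int = 500
    phase1_generations: int = 1000
    phase2_size: int = 100
    phase2_generations: int = 50
    mutation_rate: float = 2.5e-5

    def to_config(self, seed: int) -> DemographyConfig:
        return DemographyConfig(rng_seed=seed, **self.model_dump())


class PanelSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    marker_spacing_cM: float = 0.1
    n_loci: int = 2000
    window_cM: float = 1.0
    qtl_offset_cM: float = 0.3


class SampleSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n: int = 500
    qtl_variance_fraction: float = Field(0.05, ge=0.0, lt=1.0)


class BGFSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k: int = Field(1, ge=1, le=2)
    n_iterations: int = 20_000
    burn_in: int = 5_000
    thinning: int = 5
    sigma2_mu: float = 1.0
    nu_e: float = 4.0
    S2_e: float = 0.5
    sigma2_x: float = 4.0
    sigma2_x_prop: float = 0.25
    sigma2_mu_prop: float = 0.01
    sigma2_e_prop: float = 0.01


class ExperimentSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    method: str = "LSR1"
    n_null_reps: int = 1500
    n_power_reps: Optional[int] = None
    n_histories: Optional[int] = None
    level: float = 0.10


class RunConfig(BaseModel):
    """Schema-validated declarative configuration; unknown keys rejected."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    demography: DemographySection = DemographySection()
    panel: PanelSection = PanelSection()
    sample: SampleSection = SampleSection()
    bgf: BGFSection = BGFSection()
    experiment: ExperimentSection = ExperimentSection()


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def write_manifest(out_dir, config, seed: int, **extra) -> Path:
    """Record config, seed and versions so a run can be replayed exactly."""
    import scipy

    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "gfmap_version": __version__,
        "numpy_version": np.__version__,
        "scipy_version": scipy.__version__,
        "python_version": platform.python_version(),
        "seed": seed,
        "config": config.model_dump() if isinstance(config, BaseModel) else config,
        **extra,
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path
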