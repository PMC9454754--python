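"""End-to-end orchestration: one patient, then a cohort.

Pipeline per patient: read-count filtering -> VAF computation -> clone
deconvolution -> maximum-parsimony clone phylogeny -> migration-history
inference (missing-primary mode applied automatically when no primary
sample exists) -> progression and seeding classification -> migration
tallies.  Patients with fewer than three tumor samples are rejected because
deconvolution of full clone genotypes is not reliable there; patients whose
migration map averages below the support bound are flagged excluded and
dropped from cohort statistics.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from . import io as mio
from .classify import (
    ProgressionLabel,
    SeedingLabel,
    classify_migration_map,
    classify_phylogeny,
)
from .deconvolve import CloneLocationMap, CloneSet, deconvolve, estimate_purity
from .migration import MigrationMap, infer_migration_history
from .phylogeny import infer_parsimony_tree
from .stats import MigrationSummary, cohort_summary, tally_paths, write_report
from .tree import CloneNode, to_newick


class PatientRejected(ValueError):
    """Raised when a dataset fails the inclusion rules."""


@dataclass
class PipelineConfig:
    """All thresholds of the analysis; defaults are the published settings
    wherever the protocol states them."""

    min_total: int = 40
    min_variant: int = 6
    presence_eps: float = 1e-3
    max_clusters: int = 15
    containment_tol: float = 0.05
    max_resolutions: int = 30
    posterior_hi: float = 0.5
    posterior_lo: float = 0.15
    support_min: float = 0.3
    boltzmann_lambda: float = 1.0
    cost_window: int = 2
    min_samples: int = 3
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PatientResult:
    patient_id: str
    cloneset: CloneSet
    locations: CloneLocationMap
    tree: CloneNode
    migration_map: MigrationMap
    progression: ProgressionLabel
    seeding: SeedingLabel
    summary: MigrationSummary
    purity: pd.Series
    excluded: bool
    config: PipelineConfig
    site_classes: dict[str, str] = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return len({s for ss in self.locations.locations.values() for s in ss})

    @property
    def n_clones(self) -> int:
        return len(self.cloneset.clone_ids)

    @property
    def clones_per_tumor(self) -> list[int]:
        sites = sorted({s for ss in self.locations.locations.values() for s in ss})
        return [
            sum(1 for c in self.locations.locations if s in self.locations.locations[c])
            for s in sites
        ]

    @property
    def tumors_per_clone(self) -> list[int]:
        return [
            len(s) for s in self.locations.locations.values() if s
        ]

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "clones": {
                c: sorted(self.locations.locations.get(c, set()))
                for c in self.cloneset.clone_ids
            },
            "unobserved_clones": sorted(self.locations.unobserved),
            "clone_frequencies": {
                c: {s: round(float(v), 6) for s, v in row.items()}
                for c, row in self.cloneset.frequencies.iterrows()
            },
            "purity": {s: round(float(v), 6) for s, v in self.purity.items()},
            "tree_newick": to_newick(self.tree),
            "migration_map": self.migration_map.to_dict(),
            "progression": {
                "label": self.progression.label,
                "evidence": self.progression.evidence,
            },
            "seeding": {
                "label": self.seeding.label,
                "evidence": self.seeding.evidence,
            },
            "path_counts": self.summary.path_counts,
            "total_migrations": self.summary.total_migrations,
            "excluded": self.excluded,
            "config": self.config.to_dict(),
        }


def run_patient(
    snv: Union[str, Path, mio.SnvMatrix],
    samples: Union[str, Path, pd.DataFrame],
    config: Optional[PipelineConfig] = None,
    patient_id: str = "patient",
    vaf: Optional[pd.DataFrame] = None,
) -> PatientResult:
    """Run the full per-patient analysis.

    ``vaf`` overrides the filter+VAF stages with a precomputed (for
    instance analytic, noise-free) VAF matrix; the read-count matrix is
    then only used for sample bookkeeping.
    """
    config = config or PipelineConfig()
    matrix = snv if isinstance(snv, mio.SnvMatrix) else mio.read_snv_table(snv)
    sample_info = (
        samples
        if isinstance(samples, pd.DataFrame)
        else mio.read_sample_info(samples)
    )
    sample_info = mio.validate_sample_info(sample_info)
    if len(sample_info) < config.min_samples:
        raise PatientRejected(
            f"{patient_id}: {len(sample_info)} tumor samples < {config.min_samples}; "
            "deconvolution of full clone genotypes is not reliable"
        )
    site_classes = mio.site_classes_of(sample_info)

    data = vaf
    if data is None:
        data = mio.filter_snvs(matrix, config.min_total, config.min_variant)
    cloneset, locations = deconvolve(
        data,
        sample_info,
        max_clusters=config.max_clusters,
        tol=config.containment_tol,
        eps=config.presence_eps,
        seed=config.seed,
    )
    purity = estimate_purity(cloneset.frequencies)
    tree = infer_parsimony_tree(cloneset)
    missing_primary = not any(c == "primary" for c in site_classes.values())
    mmap = infer_migration_history(
        tree,
        locations,
        site_classes,
        hi=config.posterior_hi,
        lo=config.posterior_lo,
        support_min=config.support_min,
        lam=config.boltzmann_lambda,
        cost_window=config.cost_window,
        max_resolutions=config.max_resolutions,
        seed=config.seed,
        missing_primary=missing_primary,
    )
    progression = classify_phylogeny(tree, locations, mmap.site_classes)
    seeding = classify_migration_map(mmap)
    summary = tally_paths(mmap)
    return PatientResult(
        patient_id=patient_id,
        cloneset=cloneset,
        locations=locations,
        tree=tree,
        migration_map=mmap,
        progression=progression,
        seeding=seeding,
        summary=summary,
        purity=purity,
        excluded=mmap.excluded,
        config=config,
        site_classes=site_classes,
    )


@dataclass
class CohortResult:
    patients: list[PatientResult]
    summary: Optional[object]
    failures: dict[str, str]

    @property
    def n_failures(self) -> int:
        return len(self.failures)


def _read_manifest(manifest) -> list[dict]:
    if isinstance(manifest, (str, Path)):
        path = Path(manifest)
        if path.suffix in (".yaml", ".yml"):
            entries = yaml.safe_load(path.read_text())
        else:
            entries = pd.read_csv(path, sep="\t").to_dict(orient="records")
    else:
        entries = list(manifest)
    if not entries:
        raise ValueError("empty cohort manifest")
    return entries


def run_cohort(
    manifest,
    config: Optional[PipelineConfig] = None,
    out_dir: Optional[Union[str, Path]] = None,
) -> CohortResult:
    """Run every patient of a manifest and aggregate cohort statistics.

    The manifest is a list (or TSV/YAML file) of records with
    ``patient_id``, ``snv_path``, ``samples_path`` and optional per-patient
    ``max_resolutions`` overrides.  Per-patient failures are recorded and
    the cohort continues.
    """
    config = config or PipelineConfig()
    entries = _read_manifest(manifest)
    patients: list[PatientResult] = []
    failures: dict[str, str] = {}
    for entry in entries:
        pid = str(entry.get("patient_id", f"patient{len(patients)}"))
        pconfig = config
        override = entry.get("max_resolutions")
        if override is not None and not pd.isna(override):
            pconfig = PipelineConfig(**{**config.to_dict(), "max_resolutions": int(override)})
        try:
            result = run_patient(
                entry["snv_path"],
                entry["samples_path"],
                pconfig,
                patient_id=pid,
            )
            patients.append(result)
        except Exception as exc:  # noqa: BLE001 - per-patient isolation
            failures[pid] = str(exc)
    summary = None
    included = [p for p in patients if not p.excluded]
    if len(included) >= 2:
        summary = cohort_summary(patients)
    if out_dir is not None:
        write_report(patients, summary, out_dir, config=config.to_dict())
        if failures:
            (Path(out_dir) / "failures.json").write_text(
                json.dumps(failures, indent=2, sort_keys=True)
            )
    return CohortResult(patients=patients, summary=summary, failures=failures)
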