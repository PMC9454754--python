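"""Per-patient and cohort-level seeding statistics.

Every clone migration is tallied as an independent event and typed by the
site classes of its endpoints (P->M, M->M, M->P).  Ordered site pairs with
a single migrating clone are monoclonal seedings, pairs with several are
polyclonal; unordered site pairs seeded in both directions are reciprocal
clonal exchanges.  Cohort summaries aggregate the per-patient counts into
the distributions of tumors, clones, clones per tumor, tumors per clone
and purity, path-type proportions, label frequencies, and an ordinary
least-squares regression of total migrations on the number of metastatic
sites sampled.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .migration import MigrationMap, path_type_of

PATH_TYPES = ("P->M", "M->M", "M->P")


@dataclass
class MigrationSummary:
    path_counts: dict[str, int]
    pair_counts: dict[tuple[str, str], int]
    monoclonal_pairs: dict[str, int]  # keyed by source class ("P" | "M")
    polyclonal_pairs: dict[str, int]
    reciprocal_PM_pairs: list[tuple[str, str]]
    reciprocal_MM_pairs: list[tuple[str, str]]
    polyclonal_reciprocal_pairs: list[tuple[str, str]]
    total_migrations: int
    n_met_sites: int

    def check(self) -> None:
        assert sum(self.path_counts.values()) == self.total_migrations


def _summarize_pairs(
    pair_counts: dict[tuple[str, str], int],
    site_classes: dict[str, str],
    n_met_sites: int,
) -> MigrationSummary:
    path_counts = {t: 0 for t in PATH_TYPES}
    mono = {"P": 0, "M": 0}
    poly = {"P": 0, "M": 0}
    for (src, dst), k in pair_counts.items():
        ptype = path_type_of(src, dst, site_classes)
        path_counts[ptype] = path_counts.get(ptype, 0) + k
        src_class = "P" if site_classes.get(src) == "primary" else "M"
        if k == 1:
            mono[src_class] += 1
        else:
            poly[src_class] += 1

    recip_pm, recip_mm, recip_poly = [], [], []
    seen = set()
    for src, dst in pair_counts:
        key = tuple(sorted((src, dst)))
        if key in seen or (dst, src) not in pair_counts:
            continue
        seen.add(key)
        classes = {site_classes.get(src), site_classes.get(dst)}
        if classes == {"primary", "metastasis"}:
            recip_pm.append(key)
        elif classes == {"metastasis"}:
            recip_mm.append(key)
        if max(pair_counts[(src, dst)], pair_counts[(dst, src)]) >= 2:
            recip_poly.append(key)

    return MigrationSummary(
        path_counts=path_counts,
        pair_counts=dict(pair_counts),
        monoclonal_pairs=mono,
        polyclonal_pairs=poly,
        reciprocal_PM_pairs=sorted(recip_pm),
        reciprocal_MM_pairs=sorted(recip_mm),
        polyclonal_reciprocal_pairs=sorted(recip_poly),
        total_migrations=sum(path_counts.values()),
        n_met_sites=n_met_sites,
    )


def tally_paths(mmap: MigrationMap) -> MigrationSummary:
    """Tally each clone migration of a selected map as an independent event."""
    n_mets = sum(
        1
        for s in mmap.occupied_sites
        if mmap.site_classes.get(s, "metastasis") == "metastasis"
    )
    return _summarize_pairs(mmap.pair_counts(), mmap.site_classes, n_mets)


def tally_events(
    events: list[tuple[str, str, str]], site_classes: dict[str, str]
) -> MigrationSummary:
    """The same summary computed directly from a ground-truth event log."""
    pair_counts: dict[tuple[str, str], int] = {}
    for src, dst, _clone in events:
        pair_counts[(src, dst)] = pair_counts.get((src, dst), 0) + 1
    n_mets = sum(
        1
        for s in {x for e in events for x in e[:2]} | set(site_classes)
        if site_classes.get(s) == "metastasis"
    )
    return _summarize_pairs(pair_counts, site_classes, n_mets)


def detect_reciprocal_exchanges(mmap: MigrationMap) -> dict[str, list]:
    """Unordered site pairs with migrations in both directions."""
    summary = tally_paths(mmap)
    return {
        "P<->M": summary.reciprocal_PM_pairs,
        "M<->M": summary.reciprocal_MM_pairs,
        "polyclonal_return": summary.polyclonal_reciprocal_pairs,
    }


# -- cohort -----------------------------------------------------------------


@dataclass
class CohortSummary:
    distributions: dict[str, list]
    distribution_stats: pd.DataFrame
    path_type_counts: dict[str, int]
    path_type_proportions: dict[str, float]
    seeding_clonality: pd.DataFrame  # mono/poly counts by source class
    progression_frequencies: dict[str, float]
    seeding_frequencies: dict[str, float]
    regression: dict[str, float]
    n_patients: int
    excluded_patients: list[str] = field(default_factory=list)


def cohort_summary(patients: list) -> CohortSummary:
    """Aggregate per-patient results (excluded patients are dropped).

    ``patients`` is a list of :class:`~metmap.pipeline.PatientResult`-like
    objects exposing patient_id, excluded, summary, purity, clone and
    sample information.
    """
    excluded = [p.patient_id for p in patients if p.excluded]
    included = [p for p in patients if not p.excluded]
    if len(included) < 2:
        raise ValueError("cohort summary needs at least two non-excluded patients")

    tumors_per_patient = [p.n_sites for p in included]
    clones_per_patient = [p.n_clones for p in included]
    clones_per_tumor = [v for p in included for v in p.clones_per_tumor]
    tumors_per_clone = [v for p in included for v in p.tumors_per_clone]
    purity = [v for p in included for v in p.purity.tolist()]
    distributions = {
        "tumors_per_patient": tumors_per_patient,
        "clones_per_patient": clones_per_patient,
        "clones_per_tumor": clones_per_tumor,
        "tumors_per_clone": tumors_per_clone,
        "purity": purity,
    }
    rows = []
    for name, values in distributions.items():
        arr = np.asarray(values, dtype=float)
        rows.append((name, arr.mean(), float(np.median(arr)), len(arr)))
    stats_df = pd.DataFrame(rows, columns=["distribution", "mean", "median", "n"])

    path_counts = {t: 0 for t in PATH_TYPES}
    clonality = {("P", "mono"): 0, ("P", "poly"): 0, ("M", "mono"): 0, ("M", "poly"): 0}
    for p in included:
        for t in PATH_TYPES:
            path_counts[t] += p.summary.path_counts.get(t, 0)
        for cls in ("P", "M"):
            clonality[(cls, "mono")] += p.summary.monoclonal_pairs[cls]
            clonality[(cls, "poly")] += p.summary.polyclonal_pairs[cls]
    total_paths = sum(path_counts.values())
    proportions = {
        t: (path_counts[t] / total_paths if total_paths else 0.0) for t in PATH_TYPES
    }
    clonality_df = pd.DataFrame(
        [
            (cls, kind, clonality[(cls, kind)])
            for cls in ("P", "M")
            for kind in ("mono", "poly")
        ],
        columns=["source_class", "clonality", "n_site_pairs"],
    )

    def frequencies(labels: list[str]) -> dict[str, float]:
        out: dict[str, float] = {}
        for label in labels:
            out[label] = out.get(label, 0) + 1
        return {k: v / len(labels) for k, v in sorted(out.items())} if labels else {}

    progression = frequencies([p.progression.label for p in included])
    seeding = frequencies([p.seeding.label for p in included])

    x = np.asarray([p.summary.n_met_sites for p in included], dtype=float)
    y = np.asarray([p.summary.total_migrations for p in included], dtype=float)
    if np.ptp(x) == 0:
        regression = {
            "slope": float("nan"),
            "intercept": float("nan"),
            "r_squared": float("nan"),
            "degenerate": True,
        }
    else:
        fit = sps.linregress(x, y)
        regression = {
            "slope": float(fit.slope),
            "intercept": float(fit.intercept),
            "r_squared": float(fit.rvalue**2),
            "degenerate": False,
        }

    return CohortSummary(
        distributions=distributions,
        distribution_stats=stats_df,
        path_type_counts=path_counts,
        path_type_proportions=proportions,
        seeding_clonality=clonality_df,
        progression_frequencies=progression,
        seeding_frequencies=seeding,
        regression=regression,
        n_patients=len(included),
        excluded_patients=excluded,
    )


# -- reporting --------------------------------------------------------------


def write_report(
    patients: list,
    cohort: Optional[CohortSummary],
    out_dir,
    config: Optional[dict] = None,
) -> list[Path]:
    """Write per-patient JSON reports plus cohort TSVs, deterministically."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for p in patients:
        path = out / f"{p.patient_id}.json"
        path.write_text(json.dumps(p.to_dict(), indent=2, sort_keys=True))
        written.append(path)
    if cohort is not None:
        stats_path = out / "distributions.tsv"
        cohort.distribution_stats.round(6).to_csv(stats_path, sep="\t", index=False)
        written.append(stats_path)

        path_rows = [
            (t, cohort.path_type_counts[t], round(cohort.path_type_proportions[t], 6))
            for t in PATH_TYPES
        ]
        paths_path = out / "path_types.tsv"
        pd.DataFrame(path_rows, columns=["path_type", "count", "proportion"]).to_csv(
            paths_path, sep="\t", index=False
        )
        written.append(paths_path)

        labels_rows = [
            ("progression", k, round(v, 6))
            for k, v in cohort.progression_frequencies.items()
        ] + [("seeding", k, round(v, 6)) for k, v in cohort.seeding_frequencies.items()]
        labels_path = out / "labels.tsv"
        pd.DataFrame(labels_rows, columns=["classifier", "label", "frequency"]).to_csv(
            labels_path, sep="\t", index=False
        )
        written.append(labels_path)

        clonality_path = out / "seeding_clonality.tsv"
        cohort.seeding_clonality.to_csv(clonality_path, sep="\t", index=False)
        written.append(clonality_path)

        exclusions_path = out / "exclusions.tsv"
        pd.DataFrame(
            {"patient_id": cohort.excluded_patients}
        ).to_csv(exclusions_path, sep="\t", index=False)
        written.append(exclusions_path)

        regression_path = out / "regression.tsv"
        pd.DataFrame([cohort.regression]).round(6).to_csv(
            regression_path, sep="\t", index=False
        )
        written.append(regression_path)
    if config is not None:
        cfg_path = out / "run_config.json"
        cfg_path.write_text(json.dumps(config, indent=2, sort_keys=True))
        written.append(cfg_path)
    return written
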