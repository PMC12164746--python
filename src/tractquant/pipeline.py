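"""End-to-end pipeline: simulate -> profile -> analyze -> classify -> report.

A :class:`RunManifest` snapshots everything that determines a run (cohort
spec, analysis config, seed, output directory, software version); running
the same manifest twice produces byte-identical artifacts, and the written
``manifest.json`` records a sha256 checksum per output file.  No
timestamps enter any output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from . import io as tio
from .errors import DataError
from .profiles import summarize_profile
from .reporting import cohort_summary
from .simulate import CohortSpec, simulate_cohort
from .stats import AnalysisConfig, comparison_grid
from .taxonomy import classify_comparisons, intersect_pairs, taxonomy_report

log = logging.getLogger("tractquant")


@dataclass
class RunManifest:
    cohort: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "results"
    version: str = __version__
    checksums: dict = field(default_factory=dict)

    @classmethod
    def from_specs(cls, spec: CohortSpec, config: AnalysisConfig,
                   out_dir) -> "RunManifest":
        return cls(cohort=tio.cohort_spec_to_dict(spec),
                   analysis=dataclasses.asdict(config),
                   seed=spec.seed, out_dir=str(out_dir))

    def specs(self) -> tuple[CohortSpec, AnalysisConfig]:
        spec = tio.cohort_spec_from_dict(self.cohort)
        cfg = dict(self.analysis)
        if "covariates" in cfg:
            cfg["covariates"] = tuple(cfg["covariates"])
        return spec, AnalysisConfig(**cfg)

    def write(self, path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)
            + "\n", encoding="utf-8")


def _split_pairs(grid):
    by_pair: dict[str, list] = {}
    for r in grid:
        by_pair.setdefault(r.group_a, []).append(r)
    return by_pair


def run_pipeline(manifest: RunManifest) -> RunManifest:
    """Execute every stage and write all artifacts under ``out_dir``.

    Stages: cohort simulation; profile tables; presurgical and (when any
    patient was operated) postsurgical diagnosis-vs-control grids at
    combined, FLE-only and TLE-only scopes; outcome grids; taxonomy labels
    with a count report; cohort summary; manifest with checksums.  Any
    stage failure aborts with a stage-named error.
    """
    out = Path(manifest.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec, config = manifest.specs()
    fingerprint = tio.config_fingerprint(config, spec)
    written: list[Path] = []

    def emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        written.append(path)
        return path

    log.info("simulate: cohort seed=%d", spec.seed)
    subjects, profiles = simulate_cohort(spec)
    log.info("simulate: %d subjects, %d tract profiles", len(subjects),
             len(profiles))
    emit("subjects.csv", lambda p: tio.write_subjects_csv(subjects, p))
    emit("profile_nodes.csv",
         lambda p: tio.write_profiles_csv(profiles, p,
                                          out / "profile_tracts.csv"))
    written.append(out / "profile_tracts.csv")

    summaries = [summarize_profile(p, spec.n_segments)
                 for p in profiles if p.valid]
    log.info("profile: %d valid summaries", len(summaries))

    has_post = any("post" in s.timepoints_present for s in subjects
                   if s.is_patient)
    timepoints = ["pre"] + (["post"] if has_post else [])
    grids: dict[tuple[str, str], list] = {}
    for tp in timepoints:
        combined = comparison_grid(summaries, subjects, timepoint=tp,
                                   config=config)
        by_pair = _split_pairs(combined)
        grids[("combined", tp)] = intersect_pairs(
            by_pair.get("FLE", []), by_pair.get("TLE", []))
        rows = list(combined)
        for grp in ("FLE", "TLE"):
            g = comparison_grid(summaries, subjects, timepoint=tp,
                                config=config, restrict_to=grp)
            grids[(f"{grp}-only", tp)] = g
            rows += g
        n_sig = sum(r.significant for r in rows)
        log.info("analyze[%s]: %d rows, %d significant", tp, len(rows),
                 n_sig)
        emit(f"comparisons_{tp}.tsv",
             lambda p, rows=rows: tio.write_comparisons_tsv(
                 rows, p, fingerprint, manifest.version))
        emit(f"comparisons_{tp}.json", lambda p, rows=rows: Path(p).write_text(
            json.dumps({"timepoint": tp, "rows": len(rows),
                        "significant": sum(r.significant for r in rows),
                        "skipped": sum(r.skipped for r in rows),
                        "config_fingerprint": fingerprint,
                        "version": manifest.version},
                       indent=1, sort_keys=True) + "\n",
            encoding="utf-8"))
        # outcome grids (operated patients only)
        try:
            outcome = comparison_grid(summaries, subjects,
                                      grouping="outcome", timepoint=tp,
                                      config=config)
            emit(f"comparisons_outcome_{tp}.tsv",
                 lambda p, g=outcome: tio.write_comparisons_tsv(
                     g, p, fingerprint, manifest.version))
        except DataError as exc:
            log.warning("analyze[%s]: outcome grid skipped (%s)", tp, exc)

    labels = []
    not_evaluable = []
    for scope in ("combined", "FLE-only", "TLE-only"):
        pre = grids[(scope, "pre")]
        post = grids.get((scope, "post"))
        labs, nev = classify_comparisons(pre, post, cohort_scope=scope)
        labels += labs
        not_evaluable += [(scope, t, l) for t, l in nev]
    log.info("classify: %d labels, %d not-evaluable instances", len(labels),
             len(not_evaluable))
    emit("labels.tsv", lambda p: tio.write_labels(labels, p,
                                                  out / "labels.json",
                                                  fingerprint))
    written.append(out / "labels.json")
    emit("taxonomy_report.tsv",
         lambda p: taxonomy_report(labels).to_csv(p, sep="\t", index=False))
    emit("not_evaluable.tsv", lambda p: Path(p).write_text(
        "cohort_scope\ttract\tlaterality\n" + "".join(
            f"{s}\t{t}\t{l}\n" for s, t, l in not_evaluable),
        encoding="utf-8"))
    emit("cohort_summary.csv",
         lambda p: cohort_summary(subjects).to_csv(p, index=False))

    manifest.checksums = {p.name: tio.sha256_file(p)
                          for p in sorted(written)}
    manifest.write(out / "manifest.json")
    log.info("done: %d artifacts in %s", len(written) + 1, out)
    return manifest
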