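"""Reading and writing the pipeline's table formats.

The tract-profile dialect follows the AFQ nodes-table style: a long CSV
with one row per (subject, timepoint, tract, side, node) carrying FA, MD
and VOL, plus a companion per-tract CSV with the global fiber count (FIB)
and the valid flag.  All files are UTF-8 with dot decimals and mandatory
headers; floats round-trip exactly (shortest-repr formatting).  Validation
errors name the offending subject/tract and file line.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .constants import N_NODES, TRACTS
from .errors import SchemaError
from .profiles import Fiber, FiberBundle, TractProfile
from .simulate import CohortSpec, EffectSpec, NoiseSpec
from .stats import AnalysisConfig, ComparisonResult
from .subjects import SubjectRecord
from .taxonomy import AbnormalityLabel

NODE_COLUMNS = ["subject_id", "timepoint", "tract", "side", "node",
                "FA", "MD", "VOL"]
TRACT_COLUMNS = ["subject_id", "timepoint", "tract", "side", "FIB", "valid"]
SUBJECT_COLUMNS = ["subject_id", "group", "operated", "ioz_side",
                   "engel_class", "age", "sex", "duration"]


# ---------------------------------------------------------------------------
# profiles

def write_profiles_csv(profiles: Sequence[TractProfile], nodes_path,
                       tracts_path) -> None:
    node_rows = []
    tract_rows = []
    for p in profiles:
        for k in range(p.n_nodes):
            node_rows.append((p.subject_id, p.timepoint, p.tract, p.side,
                              k + 1, p.fa_nodes[k], p.md_nodes[k],
                              p.vol_nodes[k]))
        tract_rows.append((p.subject_id, p.timepoint, p.tract, p.side,
                           p.fib, p.valid))
    pd.DataFrame(node_rows, columns=NODE_COLUMNS).to_csv(
        nodes_path, index=False, float_format="%.17g")
    pd.DataFrame(tract_rows, columns=TRACT_COLUMNS).to_csv(
        tracts_path, index=False, float_format="%.17g")


def read_profiles_csv(nodes_path, tracts_path,
                      n_nodes: int = N_NODES) -> list[TractProfile]:
    """Read and validate a profile table pair.

    Raises :class:`SchemaError` naming the subject/tract for a missing
    column, a node gap, a node count other than ``n_nodes``, an FA outside
    [0, 1] or a non-positive MD.
    """
    nodes = pd.read_csv(nodes_path, float_precision="round_trip")
    tracts = pd.read_csv(tracts_path)
    for col in NODE_COLUMNS:
        if col not in nodes.columns:
            raise SchemaError(f"{nodes_path}: missing column {col!r}")
    for col in TRACT_COLUMNS:
        if col not in tracts.columns:
            raise SchemaError(f"{tracts_path}: missing column {col!r}")
    meta = {(r.subject_id, r.timepoint, r.tract, r.side): (int(r.FIB),
                                                           bool(r.valid))
            for r in tracts.itertuples()}
    profiles: list[TractProfile] = []
    if nodes.empty:
        return profiles
    for key, grp in nodes.groupby(["subject_id", "timepoint", "tract",
                                   "side"], sort=False):
        sid, tp, tract, side = key
        where = f"subject {sid!r} tract {tract!r} side {side!r} ({tp})"
        if tract not in TRACTS:
            raise SchemaError(f"{where}: unknown tract")
        grp = grp.sort_values("node")
        expected = np.arange(1, len(grp) + 1)
        if not np.array_equal(grp["node"].to_numpy(), expected):
            raise SchemaError(f"{where}: node sequence has gaps or "
                              "duplicates")
        fa = grp["FA"].to_numpy(dtype=float)
        md = grp["MD"].to_numpy(dtype=float)
        vol = grp["VOL"].to_numpy(dtype=float)
        if np.any(fa < 0) or np.any(fa > 1):
            raise SchemaError(f"{where}: FA outside [0, 1]")
        if np.any(md <= 0):
            raise SchemaError(f"{where}: MD must be positive")
        if np.any(vol < 0):
            raise SchemaError(f"{where}: VOL must be non-negative")
        if key not in meta:
            raise SchemaError(f"{where}: no matching FIB row")
        if len(grp) != n_nodes:
            raise SchemaError(
                f"{where}: expected {n_nodes} nodes, found {len(grp)}")
        fib, valid = meta[key]
        profiles.append(TractProfile(sid, tp, tract, side, fa, md, vol,
                                     fib=fib, valid=valid,
                                     n_nodes=len(grp)))
    return profiles


# ---------------------------------------------------------------------------
# subjects

def write_subjects_csv(subjects: Sequence[SubjectRecord], path) -> None:
    rows = [(s.subject_id, s.group, s.operated, s.ioz_side, s.engel_class,
             s.age, s.sex, s.epilepsy_duration) for s in subjects]
    pd.DataFrame(rows, columns=SUBJECT_COLUMNS).to_csv(
        path, index=False, float_format="%.17g")


def read_subjects_csv(path) -> list[SubjectRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in SUBJECT_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    out = []
    for r in df.itertuples():
        operated = bool(r.operated)
        tps = frozenset({"pre", "post"}) if operated else frozenset({"pre"})
        out.append(SubjectRecord(
            str(r.subject_id), str(r.group), operated=operated,
            ioz_side=str(r.ioz_side), engel_class=str(r.engel_class),
            age=float(r.age), sex=str(r.sex),
            epilepsy_duration=float(r.duration), timepoints_present=tps))
    return out


# ---------------------------------------------------------------------------
# streamline bundles (JSON-lines polylines)

def write_bundles_jsonl(bundles: Iterable[FiberBundle], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for b in bundles:
            for fiber in b.fibers:
                rec = {"subject_id": b.subject_id, "timepoint": b.timepoint,
                       "tract": b.tract, "side": b.side,
                       "voxel_size": b.voxel_size,
                       "points": fiber.points.tolist(),
                       "fa": fiber.fa.tolist(), "md": fiber.md.tolist()}
                fh.write(json.dumps(rec) + "\n")


def read_bundles_jsonl(path) -> list[FiberBundle]:
    grouped: dict[tuple, list[Fiber]] = {}
    voxel: dict[tuple, float] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                key = (rec["subject_id"], rec["timepoint"], rec["tract"],
                       rec["side"])
                fiber = Fiber(np.asarray(rec["points"], dtype=float),
                              np.asarray(rec["fa"], dtype=float),
                              np.asarray(rec["md"], dtype=float))
            except (KeyError, ValueError, TypeError) as exc:
                raise SchemaError(f"{path}:{lineno}: {exc}") from exc
            grouped.setdefault(key, []).append(fiber)
            voxel[key] = float(rec.get("voxel_size", 2.0))
    return [FiberBundle(*key, tuple(fibers), voxel_size=voxel[key])
            for key, fibers in grouped.items()]


# ---------------------------------------------------------------------------
# comparison grids and labels

def comparisons_frame(results: Sequence[ComparisonResult],
                      fingerprint: str = "", version: str = "",
                      analysis: str = "") -> pd.DataFrame:
    rows = [dataclasses.asdict(r) for r in results]
    df = pd.DataFrame(rows)
    if analysis:
        df.insert(0, "analysis", analysis)
    if fingerprint:
        df["config_fingerprint"] = fingerprint
    if version:
        df["version"] = version
    return df


def write_comparisons_tsv(results: Sequence[ComparisonResult], path,
                          fingerprint: str = "", version: str = "",
                          analysis: str = "") -> None:
    comparisons_frame(results, fingerprint, version, analysis).to_csv(
        path, sep="\t", index=False, float_format="%.17g")


def read_comparisons_tsv(path) -> list[ComparisonResult]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    out = []
    for r in df.itertuples():
        scope = r.scope
        scope = int(scope) if str(scope) != "global" else "global"
        out.append(ComparisonResult(
            r.tract, r.laterality, r.timepoint, r.variable, scope,
            r.group_a, r.group_b, int(r.n_a), int(r.n_b), float(r.mean_a),
            float(r.mean_b), float(r.p_value), int(r.direction),
            bool(r.significant), skipped=bool(r.skipped),
            note="" if pd.isna(r.note) else str(r.note)))
    return out


def write_labels(labels: Sequence[AbnormalityLabel], tsv_path,
                 json_path=None, fingerprint: str = "") -> None:
    rows = [{"tract": lab.tract, "laterality": lab.laterality,
             "cohort_scope": lab.cohort_scope, "category": lab.category,
             "timepoint": lab.timepoint,
             "variables": "|".join(sorted(lab.variables_involved)),
             "segments": "|".join(str(s)
                                  for s in sorted(lab.segments_involved)),
             "directions": "|".join(f"{v}:{d:+d}" for v, d in
                                    sorted(lab.directions.items())),
             "config_fingerprint": fingerprint}
            for lab in labels]
    pd.DataFrame(rows, columns=["tract", "laterality", "cohort_scope",
                                "category", "timepoint", "variables",
                                "segments", "directions",
                                "config_fingerprint"]).to_csv(
        tsv_path, sep="\t", index=False)
    if json_path is not None:
        payload = [{**row} for row in rows]
        Path(json_path).write_text(json.dumps(payload, indent=1,
                                              sort_keys=True) + "\n",
                                   encoding="utf-8")


# ---------------------------------------------------------------------------
# configuration

def cohort_spec_to_dict(spec: CohortSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["effects"] = [dataclasses.asdict(e) for e in spec.effects]
    return d


def cohort_spec_from_dict(d: dict) -> CohortSpec:
    d = dict(d)
    if "effects" in d:
        d["effects"] = tuple(EffectSpec(**e) for e in d["effects"])
    if "noise" in d and isinstance(d["noise"], dict):
        d["noise"] = NoiseSpec(**d["noise"])
    for key in ("age_distributions", "duration_distributions"):
        if key in d:
            d[key] = {k: tuple(v) for k, v in d[key].items()}
    if "fibers_per_tract" in d:
        d["fibers_per_tract"] = tuple(d["fibers_per_tract"])
    return CohortSpec(**d)


def load_cohort_spec(path) -> CohortSpec:
    with open(path, encoding="utf-8") as fh:
        return cohort_spec_from_dict(yaml.safe_load(fh) or {})


def dump_cohort_spec(spec: CohortSpec, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cohort_spec_to_dict(spec), fh, sort_keys=True)


def config_fingerprint(config: AnalysisConfig, spec: CohortSpec | None = None,
                       ) -> str:
    """Short stable hash of the analysis (and optionally cohort) config."""
    payload = {"analysis": dataclasses.asdict(config)}
    if spec is not None:
        payload["cohort"] = cohort_spec_to_dict(spec)
    blob = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
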