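"""Readers and writers for the package's plain-text formats.

Formats (all UTF-8, comma-separated, `.` decimal, header row mandatory):

* panel CSV    — subject_id, time_years, state, then one column per covariate;
                 one row per visit.
* profiles CSV — long format: subject_id, tract, metric, node (0-based),
                 value, tracked; an equivalent JSON layout carries subject
                 metadata (group, age, sex) alongside.
* feature CSV  — subject_id index, label column, block-prefixed features.
* results JSON — sorted keys, 2-space indent.

Schema violations are reported with the offending row or column named.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .panel import PanelDataset
from .profiles import TractProfileSet

PANEL_REQUIRED = ("subject_id", "time_years", "state")
PROFILE_REQUIRED = ("subject_id", "tract", "metric", "node", "value", "tracked")


def write_panel_csv(dataset: PanelDataset, path) -> None:
    dataset.to_dataframe().to_csv(path, index=False)


def read_panel_csv(path, covariates=None) -> PanelDataset:
    df = pd.read_csv(path)
    missing = set(PANEL_REQUIRED) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    data = PanelDataset.from_dataframe(df, covariate_names=covariates)
    # group label = first observed state per subject
    data.groups = {s.subject_id: data.states.names[s.state_idx[0]]
                   for s in data.subjects}
    return data


def write_profiles_csv(profiles: TractProfileSet, path) -> None:
    profiles.to_long_dataframe().to_csv(path, index=False)


def read_profiles_csv(path, group=None, age=None, sex=None) -> TractProfileSet:
    df = pd.read_csv(path)
    missing = set(PROFILE_REQUIRED) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    bad = ~df["metric"].isin(["FA", "MD"])
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"{path}: row {i}: unknown metric {df['metric'].iloc[i]!r}")
    return TractProfileSet.from_long_dataframe(df, group=group, age=age, sex=sex)


def write_profiles_json(profiles: TractProfileSet, path) -> None:
    obj = {
        "tracts": list(profiles.tracts),
        "n_nodes": profiles.n_nodes,
        "subjects": [
            {"subject_id": s, "group": str(profiles.group[i]),
             "age": float(profiles.age[i]), "sex": int(profiles.sex[i]),
             "tracked": profiles.tracked[i].astype(int).tolist(),
             "FA": profiles.fa[i].tolist(), "MD": profiles.md[i].tolist()}
            for i, s in enumerate(profiles.subject_ids)
        ],
    }
    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True)


def read_profiles_json(path) -> TractProfileSet:
    with open(path) as fh:
        obj = json.load(fh)
    subs = obj["subjects"]
    return TractProfileSet(
        subject_ids=[s["subject_id"] for s in subs],
        tracts=tuple(obj["tracts"]),
        fa=np.array([s["FA"] for s in subs]),
        md=np.array([s["MD"] for s in subs]),
        tracked=np.array([s["tracked"] for s in subs], dtype=bool),
        group=np.array([s["group"] for s in subs]),
        age=np.array([s["age"] for s in subs], dtype=float),
        sex=np.array([s["sex"] for s in subs], dtype=int),
    )


def write_features_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=True)


def read_features_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    if "label" not in df.columns:
        raise ValueError(f"{path}: missing 'label' column")
    return df


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# ------------------------------------------------------------------ config

def _parse_transition_keys(d: dict) -> dict:
    """Turn 'NC->aMCI' string keys into (from, to) tuples."""
    out = {}
    for k, v in d.items():
        if isinstance(k, str) and "->" in k:
            a, b = k.split("->", 1)
            out[(a.strip(), b.strip())] = v
        else:
            out[k] = v
    return out


def load_config(path):
    """Load the pipeline YAML config.

    Layout: top-level ``seed`` (mandatory) plus optional ``cohort:``,
    ``profiles:``, ``fit:``, ``tractstats:`` and ``evaluate:`` sections,
    whose fields override the corresponding dataclass defaults.
    """
    from .pipeline import PipelineConfig
    from .simulate import CohortConfig, ProfileConfig

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "seed" not in raw:
        raise ValueError(f"{path}: top-level 'seed' is mandatory")
    seed = int(raw["seed"])

    ck = dict(raw.get("cohort", {}))
    for key in ("true_rates", "true_betas"):
        if key in ck:
            ck[key] = _parse_transition_keys(ck[key])
    if "visit_gap" in ck:
        ck["visit_gap"] = tuple(ck["visit_gap"])
    cohort = CohortConfig(**ck, seed=seed) if "seed" not in ck else CohortConfig(**ck)

    pk = dict(raw.get("profiles", {}))
    for key in ("tract_names", "fa_effect_tracts", "md_effect_tracts"):
        if key in pk:
            pk[key] = tuple(pk[key])
    if "effect_window" in pk:
        pk["effect_window"] = tuple(pk["effect_window"])
    profiles = ProfileConfig(**pk, seed=seed + 1) if "seed" not in pk else ProfileConfig(**pk)

    fit = raw.get("fit", {})
    ts = raw.get("tractstats", {})
    ev = raw.get("evaluate", {})
    return PipelineConfig(
        cohort=cohort, profiles=profiles, seed=seed,
        fit_covariates=tuple(fit.get("covariates", ("age", "sex_male"))),
        test=ts.get("test", "anova"), alpha=float(ts.get("alpha", 0.05)),
        fdr=bool(ts.get("fdr", False)),
        metrics=tuple(ts.get("metrics", ("FA", "MD"))),
        max_failure_fraction=float(ts.get("max_failure_fraction", 0.25)),
        blocks=tuple(tuple(b) for b in ev.get("blocks", [["dti"], ["mm", "dti"]])),
        folds=int(ev.get("folds", 5)),
    )
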