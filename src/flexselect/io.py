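"""Patient-data CSV schema, scenario configuration and result serialisation.

Patient CSV schema (one row per patient observation)::

    arm,cohort,w,y

``arm`` is 0 for control, 1..k for experimental arms.  ``cohort`` is 1 for
interim patients with both endpoints, 2 for interim patients with the
short-term endpoint only (``y`` may be appended once observed), and 3 for
stage-2 patients (``y`` only).  Missing values are empty fields.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .design import EffectVector, NuisanceParams, SelectionVariant, TrialDesign
from .estimators import FinalData, InterimData
from .simulator import SimulationConfig

__all__ = [
    "read_patient_csv",
    "read_interim_csv",
    "read_final_csv",
    "write_interim_csv",
    "write_final_csv",
    "write_results",
    "load_config",
    "config_hash",
]

_COLUMNS = ["arm", "cohort", "w", "y"]


class SchemaError(ValueError):
    """Raised when a patient CSV violates the schema (message names the row/arm)."""


def _load_frame(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    extra = [c for c in df.columns if c not in _COLUMNS]
    if extra:
        warnings.warn(f"ignoring extra columns {extra} in {path}")
    missing = [c for c in ("arm", "cohort") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    for c in ("w", "y"):
        if c not in df.columns:
            df[c] = np.nan
    return df[_COLUMNS]


def read_interim_csv(path: str | Path) -> InterimData:
    """Read interim patient data (cohorts 1 and 2) into an InterimData container."""
    df = _load_frame(path)
    df = df[df["cohort"].isin([1, 2])]
    if df.empty:
        raise SchemaError(f"{path}: no interim (cohort 1/2) rows")
    arms = sorted(df["arm"].unique())
    if arms != list(range(len(arms))):
        raise SchemaError(f"{path}: arms must be 0..k contiguous, got {arms}")
    n1_counts = df[df["cohort"] == 1].groupby("arm").size()
    n2_counts = df[df["cohort"] == 2].groupby("arm").size()
    for counts, label in ((n1_counts, "cohort-1"), (n2_counts, "cohort-2")):
        if counts.reindex(arms).isna().any() or counts.nunique() != 1:
            bad = {int(a): int(counts.get(a, 0)) for a in arms}
            raise SchemaError(f"{path}: inconsistent {label} sizes per arm: {bad}")
    bad1 = df[(df["cohort"] == 1) & (df["w"].isna() | df["y"].isna())]
    if not bad1.empty:
        raise SchemaError(
            f"{path}: cohort-1 rows must have both w and y; "
            f"first offending row index {int(bad1.index[0])}"
        )
    bad2 = df[(df["cohort"] == 2) & df["w"].isna()]
    if not bad2.empty:
        raise SchemaError(
            f"{path}: cohort-2 rows must have w; first offending row index {int(bad2.index[0])}"
        )
    n1 = int(n1_counts.iloc[0])
    n_second = int(n2_counts.iloc[0])
    k = len(arms) - 1
    w = np.empty((k + 1, n1 + n_second))
    y = np.empty((k + 1, n1))
    y_late = np.full((k + 1, n_second), np.nan)
    for a in arms:
        c1 = df[(df["arm"] == a) & (df["cohort"] == 1)]
        c2 = df[(df["arm"] == a) & (df["cohort"] == 2)]
        w[a] = np.concatenate([c1["w"].to_numpy(), c2["w"].to_numpy()])
        y[a] = c1["y"].to_numpy()
        y_late[a] = c2["y"].to_numpy()
    has_late = np.isfinite(y_late).all()
    return InterimData(w=w, y=y, y_late=y_late if has_late else None)


def read_final_csv(path: str | Path, selected_arm: int | None = None) -> FinalData:
    """Read final-analysis data: all primary responses of the two retained arms.

    Rows from any cohort count as long as ``y`` is present; exactly two arms
    (control plus one experimental) must carry complete primary data.
    """
    df = _load_frame(path)
    df = df[df["y"].notna()]
    if df.empty:
        raise SchemaError(f"{path}: no rows with primary responses")
    arms = sorted(df["arm"].unique())
    exp_arms = [a for a in arms if a != 0]
    if 0 not in arms or len(exp_arms) != 1:
        raise SchemaError(
            f"{path}: final data must contain control plus exactly one "
            f"experimental arm, got arms {arms}"
        )
    sel = int(exp_arms[0])
    if selected_arm is not None and selected_arm != sel:
        raise SchemaError(f"{path}: expected selected arm {selected_arm}, found {sel}")
    yc = df[df["arm"] == 0]["y"].to_numpy()
    ys = df[df["arm"] == sel]["y"].to_numpy()
    if yc.size != ys.size:
        raise SchemaError(
            f"{path}: unequal final sample sizes (control {yc.size}, arm {sel} {ys.size})"
        )
    return FinalData(y_control=yc, y_selected=ys, selected_arm=sel)


def read_patient_csv(path: str | Path, kind: str = "interim"):
    """Read a patient CSV as ``kind`` = 'interim' or 'final'."""
    if kind == "interim":
        return read_interim_csv(path)
    if kind == "final":
        return read_final_csv(path)
    raise ValueError(f"unknown kind {kind!r}")


def write_interim_csv(interim: InterimData, path: str | Path) -> None:
    rows = []
    for a in range(interim.k + 1):
        for j in range(interim.n1):
            rows.append((a, 1, interim.w[a, j], interim.y[a, j]))
        for j in range(interim.n1, interim.N1):
            y_val = (
                interim.y_late[a, j - interim.n1] if interim.y_late is not None else np.nan
            )
            rows.append((a, 2, interim.w[a, j], y_val))
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def write_final_csv(final: FinalData, path: str | Path) -> None:
    rows = [(0, 3, np.nan, v) for v in final.y_control]
    rows += [(final.selected_arm, 3, np.nan, v) for v in final.y_selected]
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def config_hash(obj: Any) -> str:
    """Short deterministic hash of a JSON-serialisable configuration."""
    canon = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def write_results(obj: Any, path: str | Path, **metadata) -> None:
    """Serialise a result object (dict/dataclass-like) to JSON with metadata."""
    from dataclasses import asdict, is_dataclass

    def conv(x: Any) -> Any:
        if is_dataclass(x) and not isinstance(x, type):
            return {k: conv(v) for k, v in asdict(x).items()}
        if isinstance(x, np.ndarray):
            return x.tolist()
        if isinstance(x, (np.floating, np.integer)):
            return x.item()
        if isinstance(x, SelectionVariant):
            return x.value
        if isinstance(x, dict):
            return {k: conv(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [conv(v) for v in x]
        return x

    payload = {"results": conv(obj)}
    payload.update(metadata)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_config(path: str | Path) -> SimulationConfig:
    """Build a SimulationConfig from a YAML or JSON scenario file."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    d = raw.get("design", {})
    design = TrialDesign(
        k=int(d.get("k", 3)),
        n1=int(d.get("n1", 40)),
        N1=int(d.get("N1", 100)),
        n2=int(d.get("n2", 200)),
        alpha=float(d.get("alpha", 0.025)),
    )
    nu = raw.get("nuisance", {})
    nuisance = NuisanceParams(
        sigma=float(nu.get("sigma", 1.0)),
        sigma0=float(nu.get("sigma0", 1.0)),
        rho=float(nu.get("rho", 0.0)),
    )
    eff = raw.get("effects", {})
    effects = EffectVector(
        theta_long=tuple(eff.get("theta_long", (0.0,) * design.k)),
        theta_short=tuple(eff.get("theta_short", ())) or (0.0,) * design.k,
    )
    selection = raw.get("selection", {})
    c = raw.get("c", {})
    return SimulationConfig(
        design=design,
        nuisance=nuisance,
        effects=effects,
        selection_rule=selection.get("rule", "tilde"),
        assumed_theta_short=(
            tuple(selection["assumed_short"]) if "assumed_short" in selection else None
        ),
        c_standardised=c.get("value"),
        c_variant=(c.get("variant", "tilde") if c.get("value") is None else None),
        estimate_nuisance_params=bool(raw.get("estimate_nuisance", False)),
        n_reps=int(raw.get("n_reps", 100_000)),
        seed=int(raw.get("seed", 0)),
        engine=raw.get("engine", "sufficient"),
    )
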