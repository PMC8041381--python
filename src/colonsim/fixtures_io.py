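"""Readers and writers for the packaged delimited-text study tables.

The package ships three tab-separated fixture files (one per study table):

* ``table_drugs.tsv`` — physicochemical/biopharmaceutics drug properties
* ``table_pk.tsv`` — systemic compartmental PK parameters and first-pass extraction
* ``table_arms.tsv`` — colon study arms with observed and software-predicted outcomes

Each file starts with ``# colonsim fixture schema v1`` comment lines; empty
cells (and ``n/a``) denote genuinely missing optional values, never zeros.
"""

from __future__ import annotations

import json
import math
from importlib import resources
from pathlib import Path

import pandas as pd

from .records import Dataset, DrugRecord, PKParameters, StudyArm

DRUGS_FILE = "table_drugs.tsv"
PK_FILE = "table_pk.tsv"
ARMS_FILE = "table_arms.tsv"

#: software labels of the two vendor prediction columns in the arms fixture
VENDOR_SOFTWARE = ("gisim", "gastroplus")


def packaged_data_dir() -> Path:
    """Directory holding the fixture tables shipped with the package."""
    return Path(resources.files("colonsim") / "data")


def _read_table(path: Path, required: tuple[str, ...]) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(f"fixture file missing: {path}")
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["n/a"], dtype={"drug": str})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required columns {missing}")
    return df


def _opt(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return float(value)


def _parse_pka(token) -> list[tuple[float, str]]:
    if token is None or (isinstance(token, float) and math.isnan(token)):
        return []
    token = str(token).strip()
    if not token or token == "neutral":
        return []
    out: list[tuple[float, str]] = []
    for part in token.split(";"):
        part = part.strip()
        kind = {"a": "acid", "b": "base"}.get(part[-1])
        if kind is None:
            raise ValueError(f"cannot parse pKa token {part!r}")
        out.append((float(part[:-1]), kind))
    return out


def load_dataset(path: str | Path | None = None) -> Dataset:
    """Load a fixture directory into a validated :class:`Dataset`.

    ``path`` defaults to the packaged study tables.  Schema violations and
    unresolvable drug references raise with the offending file/rows named.
    """
    root = Path(path) if path is not None else packaged_data_dir()

    drugs_df = _read_table(
        root / DRUGS_FILE,
        ("drug", "mw_g_mol", "pka", "peff_dog_1e4_cm_s", "s_buffer_ug_ml", "s_buffer_ph", "bcs"),
    )
    drugs: list[DrugRecord] = []
    for _, row in drugs_df.iterrows():
        ph_raw = str(row["s_buffer_ph"]).strip()
        ph: float | str = ph_raw if ph_raw in ("intrinsic", "water") else float(ph_raw)
        try:
            drugs.append(
                DrugRecord(
                    name=row["drug"],
                    molecular_weight=float(row["mw_g_mol"]),
                    pka_list=_parse_pka(row["pka"]),
                    logd74=_opt(row.get("logd74")),
                    molar_density=_opt(row.get("density_g_ml")),
                    particle_radius_mean=_opt(row.get("particle_radius_um")),
                    diffusion_coefficient=_opt(row.get("diffusion_1e9_m2_s")),
                    peff_dog=_opt(row.get("peff_dog_1e4_cm_s")),
                    peff_human=_opt(row.get("peff_human_1e4_cm_s")),
                    solubility_buffer=float(row["s_buffer_ug_ml"]),
                    solubility_buffer_ph=ph,
                    solubility_fassif=_opt(row.get("s_fassif_ug_ml")),
                    bcs_class=str(row["bcs"]).strip(),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{DRUGS_FILE}: invalid row for {row['drug']!r}: {exc}") from exc

    pk_df = _read_table(root / PK_FILE, ("drug", "cl_l_h_kg", "v_l_kg"))
    pk: dict[str, PKParameters] = {}
    for _, row in pk_df.iterrows():
        eh_pct = _opt(row.get("first_pass_pct"))
        try:
            pk[row["drug"]] = PKParameters(
                clearance=float(row["cl_l_h_kg"]),
                central_volume=float(row["v_l_kg"]),
                k12=_opt(row.get("k12_1_h")),
                k21=_opt(row.get("k21_1_h")),
                k13=_opt(row.get("k13_1_h")),
                k31=_opt(row.get("k31_1_h")),
                fraction_unbound=_opt(row.get("fu")),
                first_pass_extraction=None if eh_pct is None else eh_pct / 100.0,
                body_weight=_opt(row.get("body_weight_kg")) or 12.0,
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{PK_FILE}: invalid row for {row['drug']!r}: {exc}") from exc

    arms_df = _read_table(root / ARMS_FILE, ("drug", "dose_mg", "formulation", "route"))
    arms: list[StudyArm] = []
    for idx, row in arms_df.iterrows():
        formulation = str(row["formulation"]).strip()
        if formulation == "nanosuspension":  # modeled as the suspension formulation class
            formulation = "suspension"
        def by_software(prefix: str, scale: float = 1.0) -> dict[str, float]:
            out = {}
            for software in VENDOR_SOFTWARE:
                v = _opt(row.get(f"{prefix}_{software}")) if f"{prefix}_{software}" in row else None
                if v is not None:
                    out[software] = v * scale
            return out
        try:
            arms.append(
                StudyArm(
                    drug_name=row["drug"],
                    dose=float(row["dose_mg"]),
                    formulation=formulation,
                    route=str(row["route"]).strip(),
                    observed_auc_0t=_opt(row.get("auc_obs")),
                    observed_frel_colon=_opt(row.get("frel_obs")),
                    predicted_auc_0t_by_software=by_software("auc_pred"),
                    predicted_frel_by_software=by_software("frel_pred"),
                    predicted_fabs_colon_by_software=by_software("fabs_colon_pred", 1.0)
                    if any(c.startswith("fabs_colon_pred") for c in arms_df.columns)
                    else {},
                    t_last=_opt(row.get("t_last_h")),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{ARMS_FILE}: invalid row {idx} ({row['drug']!r}): {exc}") from exc

    # fabs columns are stored in percent with a _pct suffix; remap the keys
    for arm, (_, row) in zip(arms, arms_df.iterrows()):
        fabs = {}
        for software in VENDOR_SOFTWARE:
            col = f"fabs_colon_pred_{software}_pct"
            if col in arms_df.columns:
                v = _opt(row.get(col))
                if v is not None:
                    fabs[software] = v
        arm.predicted_fabs_colon_by_software = fabs

    return Dataset(drugs=drugs, pk=pk, arms=arms)


def write_report(summary: pd.DataFrame, per_arm: pd.DataFrame, path: str | Path) -> dict[str, Path]:
    """Write an evaluation report: delimited tables plus a JSON summary.

    ``summary`` is the grouped performance table (one row per metric ×
    formulation × software cell); ``per_arm`` the long per-arm table.  Numeric
    values are serialized with ``repr`` round-trip precision so reading the
    per-arm table back reproduces the inputs to at least 12 significant
    digits.  Empty inputs are rejected.
    """
    if summary.empty or per_arm.empty:
        raise ValueError("refusing to write an empty report")
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "summary": out / "summary.tsv",
        "per_arm": out / "per_arm.tsv",
        "summary_json": out / "summary.json",
    }
    summary.to_csv(paths["summary"], sep="\t", index=False)
    per_arm.to_csv(paths["per_arm"], sep="\t", index=False)
    with open(paths["summary_json"], "w") as fh:
        json.dump(summary.to_dict(orient="records"), fh, indent=2, default=float)
    return paths


def read_per_arm(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path) / "per_arm.tsv", sep="\t")
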