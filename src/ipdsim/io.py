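"""Tabular and configuration I/O.

File dialects (all plain text):

* Dissolution CSV — long format with columns ``time_min``, ``replicate``,
  ``pct_dissolved``; medium metadata travels in leading ``# key: value``
  comment lines (ph, volume_ml, rpm, apparatus, dose_mg).
* Plasma CSV — columns ``time_h``, ``conc_ng_ml``, ``subject``, ``product``.
* Fitted Weibull parameters — JSON (one object per product).
* Model configuration — YAML with sections ``drug``, ``disposition``,
  ``elimination``, ``gi``.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .dissolution import DissolutionProfile, MediumSpec, WeibullFit, WeibullParams
from .gi_pbpk import (
    Disposition,
    GiCompartment,
    PbpkModel,
    PbpkParameters,
    PlasmaProfile,
    RenalElimination,
    TransporterKinetics,
    build_model,
    default_gi_config,
)

__all__ = [
    "ParseError",
    "read_dissolution_csv",
    "write_dissolution_csv",
    "read_plasma_csv",
    "write_plasma_csv",
    "read_weibull_json",
    "write_weibull_json",
    "load_model_config",
    "dump_model_config",
    "default_model_config_dict",
]


class ParseError(ValueError):
    """A data file does not follow the documented dialect."""


_MEDIUM_KEYS = {"ph", "volume_ml", "rpm", "apparatus", "dose_mg"}


def read_dissolution_csv(path: str | Path) -> DissolutionProfile:
    """Read a long-format dissolution CSV with ``#`` metadata header."""
    path = Path(path)
    meta: dict[str, str] = {}
    lines = path.read_text().splitlines()
    if not any(line.strip() for line in lines):
        raise ParseError(f"{path}: empty file")
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            if ":" in line:
                key, _, val = line.lstrip("# ").partition(":")
                meta[key.strip()] = val.strip()
            body_start = i + 1
        else:
            break
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: cannot parse CSV ({exc})") from exc
    required = {"time_min", "replicate", "pct_dissolved"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"{path}: missing columns {sorted(required - set(df.columns))}"
        )
    bad = df[df[["time_min", "pct_dissolved"]].isna().any(axis=1)]
    if len(bad):
        raise ParseError(f"{path}: malformed rows at index {list(bad.index)}")

    wide = df.pivot_table(
        index="replicate", columns="time_min", values="pct_dissolved"
    )
    if wide.isna().any().any():
        raise ParseError(f"{path}: replicates do not share the time grid")
    medium = None
    if _MEDIUM_KEYS & set(meta):
        medium = MediumSpec(
            ph=float(meta.get("ph", "nan")),
            volume_ml=float(meta.get("volume_ml", "nan")),
            rpm=float(meta.get("rpm", "nan")),
            apparatus=meta.get("apparatus", "unknown"),
            dose_mg=float(meta.get("dose_mg", "nan")),
        )
    return DissolutionProfile(
        times=wide.columns.to_numpy(dtype=float),
        pct_dissolved=wide.to_numpy(dtype=float),
        medium=medium,
    )


def write_dissolution_csv(profile: DissolutionProfile, path: str | Path) -> None:
    path = Path(path)
    lines = []
    if profile.medium is not None:
        m = profile.medium
        lines += [
            f"# ph: {m.ph}",
            f"# volume_ml: {m.volume_ml}",
            f"# rpm: {m.rpm}",
            f"# apparatus: {m.apparatus}",
            f"# dose_mg: {m.dose_mg}",
        ]
    lines.append("time_min,replicate,pct_dissolved")
    for r in range(profile.n_replicates):
        for t, v in zip(profile.times, profile.pct_dissolved[r]):
            lines.append(f"{t:g},{r + 1},{v:.6g}")
    path.write_text("\n".join(lines) + "\n")


def read_plasma_csv(path: str | Path) -> dict[str, PlasmaProfile]:
    """Read plasma profiles keyed by product label (subject collapsed to
    one profile per product; files with several subjects per product should
    be averaged upstream)."""
    df = pd.read_csv(path)
    required = {"time_h", "conc_ng_ml", "product"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"{path}: missing columns {sorted(required - set(df.columns))}"
        )
    out: dict[str, PlasmaProfile] = {}
    for product, grp in df.groupby("product"):
        grp = grp.sort_values("time_h")
        mean = grp.groupby("time_h", as_index=False)["conc_ng_ml"].mean()
        out[str(product)] = PlasmaProfile(
            times_h=mean["time_h"].to_numpy(dtype=float),
            conc_ng_ml=mean["conc_ng_ml"].to_numpy(dtype=float),
            dose_mg=float(grp["dose_mg"].iloc[0]) if "dose_mg" in grp else 0.0,
            subject=str(product),
        )
    return out


def write_plasma_csv(
    profiles: dict[str, PlasmaProfile], path: str | Path
) -> None:
    rows = []
    for product, prof in profiles.items():
        for t, c in zip(prof.times_h, prof.conc_ng_ml):
            rows.append(
                {
                    "time_h": t,
                    "conc_ng_ml": c,
                    "subject": prof.subject,
                    "product": product,
                    "dose_mg": prof.dose_mg,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_weibull_json(
    fits: dict[str, WeibullFit | WeibullParams], path: str | Path
) -> None:
    payload = {}
    for product, fit in fits.items():
        params = fit.params if isinstance(fit, WeibullFit) else fit
        entry = {
            "alpha": params.alpha,
            "beta": params.beta,
            "tlag": params.tlag,
            "wmax": params.wmax,
        }
        if isinstance(fit, WeibullFit):
            entry["sse"] = fit.sse
            entry["rmse"] = fit.rmse
            entry["warnings"] = list(fit.warnings)
        payload[product] = entry
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_weibull_json(path: str | Path) -> dict[str, WeibullParams]:
    payload = json.loads(Path(path).read_text())
    return {
        product: WeibullParams(
            alpha=entry["alpha"], beta=entry["beta"],
            tlag=entry.get("tlag", 0.0), wmax=entry.get("wmax", 100.0),
        )
        for product, entry in payload.items()
    }


def default_model_config_dict() -> dict:
    """The versioned default model configuration as a plain dict."""
    p = PbpkParameters()
    return {
        "schema_version": 1,
        "drug": {
            "peff_cm_per_s": p.peff_cm_per_s,
            "d_aq_cm2_per_s": p.d_aq_cm2_per_s,
            "solubility_mg_ml_by_ph": {
                str(ph): s for ph, s in p.solubility_mg_ml_by_ph
            },
            "body_weight_kg": p.body_weight_kg,
        },
        "disposition": {
            "vc_l_per_kg": p.disposition.vc_l_per_kg,
            "k12_per_h": p.disposition.k12_per_h,
            "k21_per_h": p.disposition.k21_per_h,
        },
        "elimination": {
            "filtration_cl_l_per_h": p.renal.filtration_cl_l_per_h,
            "transporters": [
                {
                    "name": t.name,
                    "vmax_mg_per_s_per_mg": t.vmax_mg_per_s_per_mg,
                    "km_mg_per_l": t.km_mg_per_l,
                    "expression_mg": t.expression_mg,
                }
                for t in p.renal.transporters
            ],
        },
        "gi": [
            {
                "label": c.label,
                "volume_ml": float(c.volume_ml),
                "ph": float(c.ph),
                "transit_rate_per_h": round(float(c.transit_rate_per_h), 6),
                "area_cm2": float(c.area_cm2),
            }
            for c in default_gi_config()
        ],
    }


def dump_model_config(path: str | Path, config: dict | None = None) -> None:
    cfg = config if config is not None else default_model_config_dict()
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def load_model_config(path: str | Path) -> PbpkModel:
    """Build a PBPK model from a YAML configuration file."""
    cfg = yaml.safe_load(Path(path).read_text())
    try:
        drug = cfg["drug"]
        disp = cfg["disposition"]
        elim = cfg["elimination"]
        gi = cfg["gi"]
    except (KeyError, TypeError) as exc:
        raise ParseError(
            f"{path}: config needs sections drug/disposition/elimination/gi"
        ) from exc
    params = PbpkParameters(
        peff_cm_per_s=float(drug["peff_cm_per_s"]),
        d_aq_cm2_per_s=float(drug.get("d_aq_cm2_per_s", 9.24e-6)),
        solubility_mg_ml_by_ph=tuple(
            (float(ph), float(s))
            for ph, s in drug["solubility_mg_ml_by_ph"].items()
        ),
        disposition=Disposition(
            vc_l_per_kg=float(disp["vc_l_per_kg"]),
            k12_per_h=float(disp["k12_per_h"]),
            k21_per_h=float(disp["k21_per_h"]),
        ),
        renal=RenalElimination(
            filtration_cl_l_per_h=float(elim["filtration_cl_l_per_h"]),
            transporters=tuple(
                TransporterKinetics(
                    name=t["name"],
                    vmax_mg_per_s_per_mg=float(t["vmax_mg_per_s_per_mg"]),
                    km_mg_per_l=float(t["km_mg_per_l"]),
                    expression_mg=float(t.get("expression_mg", 1.0)),
                )
                for t in elim["transporters"]
            ),
        ),
        body_weight_kg=float(drug.get("body_weight_kg", 68.2)),
    )
    comps = tuple(
        GiCompartment(
            label=c["label"],
            volume_ml=float(c["volume_ml"]),
            ph=float(c["ph"]),
            transit_rate_per_h=float(c["transit_rate_per_h"]),
            area_cm2=float(c["area_cm2"]),
        )
        for c in gi
    )
    return build_model(params, comps)
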