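"""Flat-file round-trips for parameter sets and model specifications."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .drug_effect import SingleDrugPD
from .interaction import GPDITerm, InteractionModel

__all__ = [
    "drugs_from_csv",
    "drugs_to_csv",
    "model_from_yaml",
    "model_to_yaml",
]


def drugs_to_csv(drugs, path) -> None:
    """Write single-drug parameter sets to a flat CSV table."""
    rows = [
        {
            "drug_id": d.drug_id,
            "form": d.form,
            "emax": d.emax,
            "ec50": d.ec50,
            "hill": d.hill,
            "slope": d.slope,
        }
        for d in drugs
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def drugs_from_csv(path) -> tuple[SingleDrugPD, ...]:
    df = pd.read_csv(Path(path))
    out = []
    for _, row in df.iterrows():
        slope = row.get("slope")
        out.append(
            SingleDrugPD(
                drug_id=str(row["drug_id"]),
                emax=float(row["emax"]),
                ec50=float(row["ec50"]),
                hill=float(row["hill"]),
                form=str(row.get("form", "sigmoid_emax")),
                slope=None if pd.isna(slope) else float(slope),
            )
        )
    return tuple(out)


def _term_to_dict(t: GPDITerm) -> dict:
    out = {
        "perpetrator": t.perpetrator_id,
        "victim": t.victim_id,
        "target": t.target_param,
        "int": t.int_value,
        "ec50_int": t.ec50_int,
        "h_int": t.h_int,
    }
    if t.modulated_pair is not None:
        out["modulated_pair"] = list(t.modulated_pair)
    return out


def model_to_yaml(model: InteractionModel, path=None) -> str:
    """Serialise an interaction model specification; round-trips losslessly."""
    spec = {
        "criterion": model.criterion,
        "drugs": [
            {
                "drug_id": d.drug_id,
                "form": d.form,
                "emax": d.emax,
                "ec50": d.ec50,
                "hill": d.hill,
                **({"slope": d.slope} if d.slope is not None else {}),
            }
            for d in model.drugs
        ],
        "terms": [_term_to_dict(t) for t in model.terms],
    }
    text = yaml.safe_dump(spec, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def model_from_yaml(source) -> InteractionModel:
    """Load a model specification from a YAML string or file path."""
    text = source
    p = Path(str(source))
    if "\n" not in str(source) and p.exists():
        text = p.read_text()
    spec = yaml.safe_load(text)
    drugs = tuple(
        SingleDrugPD(
            drug_id=d["drug_id"],
            emax=float(d.get("emax", 1.0)),
            ec50=float(d.get("ec50", 1.0)),
            hill=float(d.get("hill", 1.0)),
            form=d.get("form", "sigmoid_emax"),
            slope=float(d["slope"]) if "slope" in d else None,
        )
        for d in spec["drugs"]
    )
    terms = tuple(
        GPDITerm(
            perpetrator_id=t["perpetrator"],
            victim_id=t["victim"],
            int_value=float(t["int"]),
            ec50_int=float(t["ec50_int"]),
            h_int=float(t.get("h_int", 1.0)),
            target_param=t.get("target", "EC50"),
            modulated_pair=tuple(t["modulated_pair"]) if "modulated_pair" in t else None,
        )
        for t in spec.get("terms", [])
    )
    return InteractionModel(drugs=drugs, terms=terms,
                            criterion=spec.get("criterion", "bliss"))
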