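"""Reading and writing model files, measurement tables and result records.

The canonical model interchange format is a JSON document:

    {
      "species": [{"name": "A", "initial_concentration": 2.0}, ...],
      "reactions": [
        {"reactants": {"A": 1}, "products": {"B": 1},
         "k_forward": 2.0, "k_reverse": 1.0},
        ...
      ],
      "t_max": 1.0,
      "perturbations": [{"species": "A", "pi": 198.0}, ...]   # optional
    }

Irreversible reactions (missing or non-positive ``k_reverse``) are
rejected at load time: a closed system admits only reversible reactions.
Measurements travel as CSV with header
``kind,perturbation,time,species,log_measurement`` (natural-log values),
with the steady-state block marked ``kind=steady``.  Floats are written
with 17 significant digits so round trips are lossless.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .posterior import MeasurementSet
from .reaction_model import ExperimentDesign, KineticParameters, ReactionNetwork

__all__ = [
    "ModelFormatError",
    "read_model",
    "write_model",
    "read_measurements",
    "write_measurements",
]

_FLOAT_FMT = "%.17g"


class ModelFormatError(ValueError):
    """Raised when a model or measurement file violates the schema."""


def _fmt(x: float) -> str:
    return _FLOAT_FMT % float(x)


def read_model(
    path: str | Path,
) -> tuple[ReactionNetwork, KineticParameters, ExperimentDesign]:
    """Parse a model JSON file into network, log-rates and design defaults."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"{path}: not valid JSON ({exc})") from exc
    for key in ("species", "reactions", "t_max"):
        if key not in doc:
            raise ModelFormatError(f"{path}: missing required field {key!r}")
    names = []
    conc = []
    for i, sp in enumerate(doc["species"]):
        if "name" not in sp or "initial_concentration" not in sp:
            raise ModelFormatError(f"{path}: species[{i}] needs name and initial_concentration")
        names.append(str(sp["name"]))
        conc.append(float(sp["initial_concentration"]))
    if len(set(names)) != len(names):
        raise ModelFormatError(f"{path}: duplicate species names")
    n = len(names)
    m = len(doc["reactions"])
    nu = np.zeros((n, m), dtype=int)
    nup = np.zeros((n, m), dtype=int)
    rates = np.empty(2 * m)
    idx = {name: i for i, name in enumerate(names)}
    for j, rxn in enumerate(doc["reactions"]):
        for side, mat in (("reactants", nu), ("products", nup)):
            for name, coeff in rxn.get(side, {}).items():
                if name not in idx:
                    raise ModelFormatError(
                        f"{path}: reactions[{j}].{side} references unknown species {name!r}"
                    )
                mat[idx[name], j] = int(coeff)
        kf = rxn.get("k_forward")
        kr = rxn.get("k_reverse")
        if kf is None or kr is None or float(kf) <= 0 or float(kr) <= 0:
            raise ModelFormatError(
                f"{path}: reactions[{j}] must declare positive k_forward and "
                "k_reverse — irreversible reactions are thermodynamically "
                "impossible in a closed system"
            )
        rates[2 * j] = float(kf)
        rates[2 * j + 1] = float(kr)
    try:
        net = ReactionNetwork(tuple(names), nu, nup)
    except ValueError as exc:
        raise ModelFormatError(f"{path}: {exc}") from exc
    perturbations: dict[int, float] = {}
    for k, pert in enumerate(doc.get("perturbations", [])):
        if "species" not in pert or "pi" not in pert:
            raise ModelFormatError(f"{path}: perturbations[{k}] needs species and pi")
        if pert["species"] not in idx:
            raise ModelFormatError(
                f"{path}: perturbations[{k}] references unknown species "
                f"{pert['species']!r}"
            )
        perturbations[idx[pert["species"]] + 1] = float(pert["pi"])
    try:
        design = ExperimentDesign(
            initial_concentrations=np.asarray(conc),
            perturbations=perturbations,
            t_max=float(doc["t_max"]),
        )
    except (ValueError, KeyError) as exc:
        raise ModelFormatError(f"{path}: {exc}") from exc
    return net, KineticParameters.from_rates(rates), design


def write_model(
    path: str | Path,
    net: ReactionNetwork,
    kappa: KineticParameters,
    design: ExperimentDesign,
) -> None:
    """Serialize a model back to the canonical JSON form."""
    doc: dict = {
        "species": [
            {"name": name, "initial_concentration": float(c)}
            for name, c in zip(net.species_names, design.initial_concentrations)
        ],
        "reactions": [],
        "t_max": float(design.t_max),
    }
    rates = kappa.rates
    for j in range(net.n_reactions):
        rxn = {
            "reactants": {
                net.species_names[i]: int(net.reactant_stoich[i, j])
                for i in np.nonzero(net.reactant_stoich[:, j])[0]
            },
            "products": {
                net.species_names[i]: int(net.product_stoich[i, j])
                for i in np.nonzero(net.product_stoich[:, j])[0]
            },
            "k_forward": float(rates[2 * j]),
            "k_reverse": float(rates[2 * j + 1]),
        }
        doc["reactions"].append(rxn)
    if design.perturbations:
        doc["perturbations"] = [
            {"species": net.species_names[p - 1], "pi": float(pi)}
            for p, pi in design.perturbations.items()
        ]
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def write_measurements(data: MeasurementSet, path: str | Path, net: ReactionNetwork) -> None:
    """Write a measurement set as the canonical CSV (natural-log values)."""
    rows = [("kind", "perturbation", "time", "species", "log_measurement")]
    for j, p in enumerate(data.design.labels):
        for q, t in enumerate(data.transient_times):
            for i, name in enumerate(net.species_names):
                rows.append(
                    ("transient", str(p), _fmt(t), name, _fmt(data.transient[i, j, q]))
                )
        for i, name in enumerate(net.species_names):
            rows.append(
                ("steady", str(p), _fmt(data.steady_time), name, _fmt(data.steady[i, j]))
            )
    with open(path, "w", newline="") as fh:
        csv.writer(fh).writerows(rows)


def read_measurements(
    path: str | Path, design: ExperimentDesign, net: ReactionNetwork
) -> MeasurementSet:
    """Load a measurement CSV and check completeness against the design.

    Every (species, perturbation, time-index) transient cell and every
    (species, perturbation) steady cell must appear exactly once; missing
    cells are reported by name, duplicates and unknown labels rejected.
    """
    path = Path(path)
    labels = design.labels
    label_col = {p: j for j, p in enumerate(labels)}
    sp_idx = {name: i for i, name in enumerate(net.species_names)}
    tran: dict[tuple[int, int], list[tuple[float, float]]] = {}
    steady = np.full((net.n_species, len(labels)), np.nan)
    steady_time = None
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"kind", "perturbation", "time", "species", "log_measurement"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ModelFormatError(f"{path}: header must contain {sorted(required)}")
        for ln, row in enumerate(reader, start=2):
            sp = row["species"]
            if sp not in sp_idx:
                raise ModelFormatError(f"{path}:{ln}: unknown species {sp!r}")
            try:
                p = int(row["perturbation"])
            except ValueError:
                raise ModelFormatError(
                    f"{path}:{ln}: bad perturbation label {row['perturbation']!r}"
                ) from None
            if p not in label_col:
                raise ModelFormatError(
                    f"{path}:{ln}: perturbation {p} not in design labels {labels}"
                )
            t = float(row["time"])
            v = float(row["log_measurement"])
            i, j = sp_idx[sp], label_col[p]
            if row["kind"] == "steady":
                if not np.isnan(steady[i, j]):
                    raise ModelFormatError(
                        f"{path}:{ln}: duplicate steady row for ({sp}, p={p})"
                    )
                steady[i, j] = v
                steady_time = t
            elif row["kind"] == "transient":
                tran.setdefault((i, j), []).append((t, v))
            else:
                raise ModelFormatError(f"{path}:{ln}: unknown kind {row['kind']!r}")
    if steady_time is None:
        raise ModelFormatError(f"{path}: no steady-state block")
    missing = [
        f"(species={net.species_names[i]}, p={labels[j]})"
        for i in range(net.n_species)
        for j in range(len(labels))
        if np.isnan(steady[i, j])
    ]
    if missing:
        raise ModelFormatError(f"{path}: missing steady rows: {', '.join(missing)}")
    # establish the common transient time grid from the first series
    ref = sorted(tran.get((0, 0), []))
    times = np.array([t for t, _ in ref])
    if times.size == 0:
        raise ModelFormatError(f"{path}: no transient block")
    Q = times.size
    transient = np.full((net.n_species, len(labels), Q), np.nan)
    for (i, j), series in tran.items():
        if len(series) != Q:
            raise ModelFormatError(
                f"{path}: transient series for (species={net.species_names[i]}, "
                f"p={labels[j]}) has {len(series)} rows, expected {Q}"
            )
        for t, v in sorted(series):
            q = int(np.argmin(np.abs(times - t)))
            if not np.isclose(times[q], t):
                raise ModelFormatError(
                    f"{path}: transient time {t} for species "
                    f"{net.species_names[i]} not on the common grid"
                )
            if not np.isnan(transient[i, j, q]):
                raise ModelFormatError(
                    f"{path}: duplicate transient row (species="
                    f"{net.species_names[i]}, p={labels[j]}, t={t})"
                )
            transient[i, j, q] = v
    bad = np.argwhere(np.isnan(transient))
    if bad.size:
        i, j, q = bad[0]
        raise ModelFormatError(
            f"{path}: missing transient rows, first: (species="
            f"{net.species_names[i]}, p={labels[j]}, t={times[q]})"
        )
    design_with_times = ExperimentDesign(
        initial_concentrations=design.initial_concentrations,
        perturbations=design.perturbations,
        t_max=design.t_max,
        transient_times=times,
        steady_state_time=steady_time,
    )
    return MeasurementSet(
        transient=transient,
        steady=steady,
        design=design_with_times,
        transient_times=times,
        steady_time=steady_time,
    )
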