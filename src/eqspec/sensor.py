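"""Built-in dye/receptor/Zn/pyrophosphate sensing models and workflows.

Exposes the chemical content of the modelled sensing ensemble as executable
objects: the ten separable sub-mechanisms, the full assembly model, the
generating thermodynamic parameter sets, the named parameter-recovery
experiment designs, and the speciation-vs-pH prediction.

Component basis (fixed order): ARS (the catechol dye, trianion), 1 (the
DPA-phenylboronic-acid receptor, anion), PPi (pyrophosphate tetraanion),
H (proton), Zn.  Charges live in names only.
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import WorkflowError
from .model import (
    DEFAULT_WATER,
    Component,
    EquilibriumModel,
    Species,
    compose_species,
)
from .fitting import FitResult, FitSpec, newton_gauss_fit
from .speciation import solve_free_concentrations
from .titration import (
    TitrationDataset,
    add_noise,
    augment,
    protocol_from_dict,
    simulate_titration,
)

COMPONENTS = ("ARS", "1", "PPi", "H", "Zn")
PROTON = "H"

#: Species whose published formation constant is defined against hydroxide;
#: stored proton-basis thermodynamics are the table values composed with the
#: water autoprotolysis step (dH + dH_w, dS + dS_w).
_OH_BASIS_OFFSET = DEFAULT_WATER  # (dH_w, dS_w)

#: Untabulated minor adducts dropped from solvable models (their equilibrium
#: concentrations never exceed trace levels under the studied conditions, so
#: their parameters are not obtainable and the models are truncated).
MINOR_SPECIES = {
    "H3ARS1Znb": (1, 1, 0, 3, 1),
    "HARS1Znb": (1, 1, 0, 1, 1),
}

_SUBMODEL_SPECIES = {
    "ars_protonation": ["HARS", "H2ARS"],
    "one_protonation": ["H1", "H21"],
    "ppi_protonation": ["HPPi", "H2PPi", "H3PPi", "H4PPi"],
    "zn_ppi": ["HPPi", "H2PPi", "H3PPi", "H4PPi", "ZnPPi", "ZnHPPi", "ZnOHPPi"],
    "zn_ars": ["HARS", "H2ARS", "ZnARS", "ZnARS2"],
    "zn_one": ["H1", "H21", "1Zn", "H1Zn", "H21Zn"],
    "h3_one_zn_ppi": [
        "H1", "H21", "1Zn", "H1Zn", "H21Zn",
        "HPPi", "H2PPi", "H3PPi", "H4PPi",
        "ZnPPi", "ZnHPPi", "ZnOHPPi", "H31ZnPPi",
    ],
    "ars_one": [
        "HARS", "H2ARS", "H1", "H21",
        "H3ARS1", "H2ARS1a", "H2ARS1b", "HARS1a",
    ],
    "ars_one_zn": [
        "HARS", "H2ARS", "H1", "H21", "1Zn", "H1Zn", "H21Zn",
        "ZnARS", "ZnARS2",
        "H3ARS1Zna", "H2ARS1Zna", "H2ARS1Znb", "H2ARS1Znc", "HARS1Zna",
    ],
}
# The full assembly model follows the printed closing mass balances: it is
# the Zn-containing assembly set plus everything the pyrophosphate brings in
# and the two ternary sensing species.  The Zn-free dye-receptor adducts
# belong only to the separable dye-receptor sub-mechanism (where their
# thermodynamics are determined); in the assembled sensor the receptor is
# zinc-bound and those adducts are absent from the printed balances.
_SUBMODEL_SPECIES["full"] = sorted(
    (set().union(*_SUBMODEL_SPECIES.values())
     | {"H3ARS1Zna", "H2ARS1Zna", "H2ARS1Znb", "H2ARS1Znc", "HARS1Zna",
        "H4ARS1ZnPPia", "H4ARS1ZnPPib"})
    - {"H3ARS1", "H2ARS1a", "H2ARS1b", "HARS1a"}
)

#: Extra (untabulated) species appearing only in the structural, untruncated
#: variants of the assembly models.
_SUBMODEL_MINOR = {
    "ars_one_zn": ["H3ARS1Znb", "HARS1Znb"],
    "full": ["H3ARS1Znb", "HARS1Znb"],
}

SUBMODEL_IDS = tuple(_SUBMODEL_SPECIES)


def _data_path(name: str):
    return resources.files("eqspec.data") / name


def parameter_set(zn_adduct_rule: str = "inherit", table: pd.DataFrame | None = None) -> dict:
    """Generating thermodynamics: species name -> :class:`Species` over the
    five-component basis.

    Tabulated entries come from the shipped table.  The Zn-bearing
    dye-receptor adducts have no tabulated thermodynamics; they are composed
    from the corresponding Zn-free adduct under the stated assumption that
    the boronic-acid binding of the dye is unchanged by the bound zinc:

    * ``"inherit"`` (default) — the Zn attachment is thermodynamically
      neutral: the adduct keeps the parent's (dH, dS).  This reproduces the
      published behaviour (the tabulated (1,1,0,2,1) adduct is recoverable
      and the ternary sensing complex is a major species).
    * ``"additive"`` — the full Zn-DPA binding step of the receptor is added
      on top of the parent.  Under this reading the composed adducts swamp
      their tabulated same-stoichiometry partner by four orders of
      magnitude, which contradicts the published recovery.
    """
    if zn_adduct_rule not in ("inherit", "additive"):
        raise WorkflowError(f"unknown zn_adduct_rule {zn_adduct_rule!r}")
    if table is None:
        table = pd.read_csv(_data_path("sensor_species.csv"), comment="#")
    species: dict = {}
    for _, row in table.iterrows():
        dh, ds = float(row["dH"]), float(row["dS"])
        if row["basis"] == "OH":
            dh += _OH_BASIS_OFFSET[0]
            ds += _OH_BASIS_OFFSET[1]
        species[row["species"]] = Species(
            row["species"],
            tuple(int(row[c]) for c in COMPONENTS),
            dh=dh,
            ds=ds,
        )
    if zn_adduct_rule == "additive":
        zn_step = Species(
            "1Zn_step", (0, 0, 0, 0, 1), dh=species["1Zn"].dh, ds=species["1Zn"].ds
        )
    else:
        zn_step = Species("1Zn_attach", (0, 0, 0, 0, 1), dh=0.0, ds=0.0)
    for base, derived in [
        ("H3ARS1", "H3ARS1Zna"),
        ("H2ARS1a", "H2ARS1Zna"),
        ("H2ARS1b", "H2ARS1Znb"),
        ("HARS1a", "HARS1Zna"),
    ]:
        if base in species:
            species[derived] = compose_species(species[base], zn_step, name=derived)
    for name, stoich in MINOR_SPECIES.items():
        species[name] = Species(name, stoich)
    return species


def reporting_basis(name: str, dh: float, ds: float) -> tuple:
    """Convert stored proton-basis thermodynamics back to the published basis."""
    table = pd.read_csv(_data_path("sensor_species.csv"), comment="#")
    row = table[table["species"] == name]
    if len(row) and row.iloc[0]["basis"] == "OH":
        return dh - _OH_BASIS_OFFSET[0], ds - _OH_BASIS_OFFSET[1]
    return dh, ds


def make_submodel(
    submodel_id: str,
    include_minor: bool = False,
    params: Mapping | None = None,
    zn_adduct_rule: str = "inherit",
) -> EquilibriumModel:
    """Build one of the named sub-mechanism models (or ``"full"``).

    Components not referenced by any of the sub-mechanism's species are
    dropped, so each sub-model lives in its minimal basis.  ``include_minor``
    adds the untabulated trace adducts (structural inspection only; they
    carry no thermodynamics and the model cannot be solved).  ``params``
    optionally overrides the generating :func:`parameter_set`.
    """
    if submodel_id not in _SUBMODEL_SPECIES:
        raise WorkflowError(
            f"unknown sub-model {submodel_id!r}; known: {sorted(_SUBMODEL_SPECIES)}"
        )
    pool = dict(parameter_set(zn_adduct_rule))
    if params:
        pool.update(params)
    names = list(_SUBMODEL_SPECIES[submodel_id])
    if include_minor:
        names += _SUBMODEL_MINOR.get(submodel_id, [])
    chosen = [pool[n] for n in names]
    used = [
        i
        for i, comp in enumerate(COMPONENTS)
        if comp == PROTON or any(sp.stoich[i] != 0 for sp in chosen)
    ]
    comps = [
        Component(COMPONENTS[i], role="proton" if COMPONENTS[i] == PROTON else "generic")
        for i in used
    ]
    reduced = [
        replace(sp, stoich=tuple(sp.stoich[i] for i in used)) for sp in chosen
    ]
    return EquilibriumModel(comps, reduced)


# -- experiment designs ------------------------------------------------------

@dataclass
class ExperimentDesign:
    """One named recovery experiment: model, curves, free parameters, noise."""

    design_id: str
    model_id: str
    free: list               # [(species, "dh"|"ds"), ...]
    curves: list             # TitrationProtocol list
    noise_sd: float
    guess_rel: dict          # {"dh": rel, "ds": rel}


def _parse_free(entries) -> list:
    out = []
    for entry in entries:
        if ":" in str(entry):
            name, which = str(entry).split(":")
            out.append((name, which.lower()))
        else:
            out.append((str(entry), "dh"))
            out.append((str(entry), "ds"))
    return out


def load_designs() -> dict:
    """All built-in experiment designs, keyed by id."""
    with (_data_path("designs.yaml")).open() as fh:
        raw = yaml.safe_load(fh)
    designs = {}
    for key, doc in raw.items():
        if "curves" not in doc:
            continue  # prediction scenarios handled separately
        curves = []
        for cdoc in doc["curves"]:
            curves.append(protocol_from_dict(cdoc))
        designs[key] = ExperimentDesign(
            design_id=key,
            model_id=doc["model"],
            free=_parse_free(doc["free"]),
            curves=curves,
            noise_sd=float(doc.get("noise_sd", 0.002)),
            guess_rel={"dh": float(doc.get("guess_rel", {}).get("dh", 0.05)),
                       "ds": float(doc.get("guess_rel", {}).get("ds", 0.05))},
        )
    return designs


def get_design(design_id: str) -> ExperimentDesign:
    designs = load_designs()
    if design_id not in designs:
        raise WorkflowError(
            f"unknown design {design_id!r}; known: {sorted(designs)}"
        )
    return designs[design_id]


def load_prediction_scenario(key: str = "predict_default") -> dict:
    with (_data_path("designs.yaml")).open() as fh:
        raw = yaml.safe_load(fh)
    if key not in raw or "ph_range" not in raw[key]:
        raise WorkflowError(f"unknown prediction scenario {key!r}")
    return raw[key]


def simulate_design(design: ExperimentDesign, seed: int | None = None,
                    n_points: int | None = None,
                    noise_sd: float | None = None) -> TitrationDataset:
    """Simulate every curve of a design at the generating truth and add noise.

    ``n_points`` overrides the per-curve aliquot count (total added volume
    preserved) — used to scale test workloads.  ``noise_sd`` overrides the
    design's noise level (0 gives the clean dataset).
    """
    model = make_submodel(design.model_id)
    datasets = []
    for proto in design.curves:
        if n_points is not None and n_points != len(proto.aliquots):
            total = sum(proto.aliquots)
            proto = replace(proto, aliquots=(total / n_points,) * n_points)
        datasets.append(simulate_titration(model, proto))
    clean = augment(datasets)
    sd = design.noise_sd if noise_sd is None else noise_sd
    if sd > 0 and seed is not None:
        return add_noise(clean, sd, seed)
    return clean


@dataclass
class RecoveryResult:
    """Fit outcome of a recovery design plus a truth-vs-fitted report table."""

    design_id: str
    fit: FitResult
    report: pd.DataFrame

    def fitted(self, species: str, which: str) -> float:
        return self.fit.value_of(species, which)


def run_recovery(
    design, seed: int, n_points: int | None = None,
    guess_rel: Mapping | None = None,
    noise_sd: float | None = None,
) -> RecoveryResult:
    """Simulate a design with the generating truth, add seeded noise, and fit.

    Initial guesses are the generating values offset by the design's relative
    perturbations.  All non-free species (and water) stay fixed at truth.
    Returns the fit plus a report with one row per fitted parameter:
    generating value, fitted value, standard error, signed accuracy (%).
    """
    if isinstance(design, str):
        design = get_design(design)
    model = make_submodel(design.model_id)
    dataset = simulate_design(design, seed=seed, n_points=n_points, noise_sd=noise_sd)
    rel = dict(design.guess_rel)
    if guess_rel:
        rel.update(guess_rel)
    truth = np.array([getattr(model[n], w) for n, w in design.free])
    guesses = np.array(
        [t * (1.0 + rel[w]) for t, (n, w) in zip(truth, design.free)]
    )
    spec = FitSpec(
        model=model,
        dataset=dataset,
        free_params=list(design.free),
        initial_guesses=guesses,
    )
    fit = newton_gauss_fit(spec, truth=truth)
    rows = []
    for k, (name, which) in enumerate(fit.free_params):
        t_dh, t_ds = reporting_basis(
            name,
            truth[k] if which == "dh" else 0.0,
            truth[k] if which == "ds" else 0.0,
        )
        f_dh, f_ds = reporting_basis(
            name,
            fit.p_hat[k] if which == "dh" else 0.0,
            fit.p_hat[k] if which == "ds" else 0.0,
        )
        t_rep = t_dh if which == "dh" else t_ds
        f_rep = f_dh if which == "dh" else f_ds
        rows.append({
            "species": name,
            "param": {"dh": "dH", "ds": "dS"}[which],
            "truth": t_rep,
            "fitted": f_rep,
            "sigma": fit.sigma_p[k] if fit.sigma_p is not None else np.nan,
            "accuracy_pct": 100.0 * (f_rep - t_rep) / t_rep if t_rep else np.nan,
        })
    report = pd.DataFrame(rows)
    report.attrs["ssq"] = fit.ssq
    report.attrs["m"] = fit.m
    return RecoveryResult(design.design_id, fit, report)


# -- speciation-vs-pH prediction --------------------------------------------

def predict_speciation_vs_ph(
    model: EquilibriumModel,
    totals: Mapping,
    T: float,
    ph_grid: Sequence[float],
) -> pd.DataFrame:
    """Species concentration profiles over an imposed pH grid.

    At each grid point the free proton concentration is clamped to
    ``10**-pH`` and the remaining mass balances are solved; the proton total
    that realises each pH is reported in the ``tot_H`` column.  ``totals``
    gives the analytical totals of the non-proton components.
    """
    ph_grid = np.asarray(ph_grid, dtype=float)
    rows = np.empty((len(ph_grid), model.n_species))
    tot_h = np.empty(len(ph_grid))
    guess = None
    h_index = model.proton_index
    for i, ph in enumerate(ph_grid):
        state = solve_free_concentrations(
            model,
            {k: v for k, v in totals.items() if k != PROTON},
            T,
            initial_guess=guess,
            fixed_free={PROTON: 10.0 ** (-ph)},
        )
        rows[i] = state.species_conc
        tot_h[i] = state.totals_calc[h_index]
        guess = state.free.copy()
        guess[guess <= 0] = 1e-30
    df = pd.DataFrame(rows, columns=model.species_names, index=pd.Index(ph_grid, name="pH"))
    df["tot_H"] = tot_h
    return df


def peak_ph(profiles: pd.DataFrame, species: str) -> float:
    """pH at which ``species`` reaches its maximal concentration."""
    return float(profiles[species].idxmax())
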