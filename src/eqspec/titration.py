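"""Potentiometric titration simulation and dataset handling.

A protocol describes one titration: initial vessel contents, titrant
composition, and an aliquot schedule.  Total concentrations follow the
dilution formula; at every point the speciation solver yields the pH.
Datasets are block-structured so curves recorded at different temperatures
and conditions can be augmented into a single global-analysis target.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import SolverError
from .model import EquilibriumModel
from .speciation import ph_of, solve_free_concentrations


@dataclass
class TitrationProtocol:
    """One titration experiment: vessel, titrant, aliquot schedule, temperature."""

    label: str
    T: float                      # kelvin
    v0: float                     # initial volume, L
    initial_totals: dict          # mol/L in the vessel at v = 0
    titrant_totals: dict          # mol/L of the titrant
    aliquots: tuple               # added volumes, L

    def __post_init__(self):
        if self.v0 <= 0:
            raise ValueError("initial volume must be positive")
        self.aliquots = tuple(float(a) for a in self.aliquots)
        if any(a <= 0 for a in self.aliquots):
            raise ValueError("aliquot volumes must be positive")

    @classmethod
    def equal_aliquots(
        cls, label, T, v0, initial_totals, titrant_totals, n: int, vstep: float
    ) -> "TitrationProtocol":
        """Protocol with ``n`` equal aliquots of ``vstep`` litres."""
        return cls(label, T, v0, dict(initial_totals), dict(titrant_totals), (vstep,) * n)

    @property
    def n_points(self) -> int:
        return len(self.aliquots) + 1

    @property
    def cumulative_volumes(self) -> np.ndarray:
        """Cumulative added titrant volume at each point (point 0 = 0)."""
        return np.concatenate([[0.0], np.cumsum(self.aliquots)])


def totals_trajectory(protocol: TitrationProtocol, components: Sequence[str]) -> np.ndarray:
    """Per-point total concentrations (n_points x n_components).

    After cumulative added volume v, totals_k = (V0*init_k + v*titr_k)/(V0+v).
    """
    v = protocol.cumulative_volumes[:, None]
    init = np.array([float(protocol.initial_totals.get(c, 0.0)) for c in components])
    titr = np.array([float(protocol.titrant_totals.get(c, 0.0)) for c in components])
    return (protocol.v0 * init + v * titr) / (protocol.v0 + v)


@dataclass
class TitrationBlock:
    """One simulated or measured curve plus its totals trajectory."""

    protocol: TitrationProtocol
    totals: np.ndarray       # n_points x n_components
    ph: np.ndarray           # measured / noisy pH, n_points
    clean_ph: np.ndarray | None = None
    species_conc: np.ndarray | None = None  # n_points x n_species, simulation only

    @property
    def T(self) -> float:
        return self.protocol.T

    @property
    def n_points(self) -> int:
        return len(self.ph)


@dataclass
class TitrationDataset:
    """Block-structured collection of titration curves over one component basis."""

    blocks: list
    components: tuple
    kind: str = "clean"       # clean | noisy | measured
    noise_sd: float = 0.0
    seed: int | None = None

    @property
    def m(self) -> int:
        """Total number of pH values across all blocks."""
        return sum(b.n_points for b in self.blocks)

    @property
    def ph(self) -> np.ndarray:
        return np.concatenate([b.ph for b in self.blocks])


def simulate_titration(
    model: EquilibriumModel, protocol: TitrationProtocol
) -> TitrationDataset:
    """Solve the speciation at every trajectory point and record clean pH.

    Consecutive points are warm-started from the previous solution.
    """
    comps = model.component_names
    totals = totals_trajectory(protocol, comps)
    n = totals.shape[0]
    ph = np.empty(n)
    conc = np.empty((n, model.n_species))
    guess = None
    for i in range(n):
        try:
            state = solve_free_concentrations(
                model, totals[i], protocol.T, initial_guess=guess
            )
        except SolverError as exc:
            raise SolverError(
                f"titration {protocol.label!r} failed at point {i} "
                f"(totals {dict(zip(comps, totals[i]))})",
                state=exc.state,
            ) from exc
        ph[i] = ph_of(state)
        conc[i] = state.species_conc
        guess = state.free.copy()
        # zero free concentrations cannot seed a log-domain warm start
        guess[guess <= 0] = 1e-30
    block = TitrationBlock(protocol, totals, ph, clean_ph=ph.copy(), species_conc=conc)
    return TitrationDataset([block], tuple(comps), kind="clean")


def add_noise(dataset: TitrationDataset, sd: float, seed: int | None = None) -> TitrationDataset:
    """Independent Gaussian pH noise on every point; clean data retained."""
    if sd < 0:
        raise ValueError("noise SD must be non-negative")
    rng = np.random.default_rng(seed)
    blocks = []
    for b in dataset.blocks:
        clean = b.clean_ph if b.clean_ph is not None else b.ph
        noisy = clean + rng.normal(0.0, sd, size=clean.shape) if sd > 0 else clean.copy()
        blocks.append(
            TitrationBlock(b.protocol, b.totals, noisy, clean_ph=clean.copy(),
                           species_conc=b.species_conc)
        )
    return TitrationDataset(
        blocks, dataset.components, kind="noisy", noise_sd=sd, seed=seed
    )


def augment(datasets: Sequence[TitrationDataset]) -> TitrationDataset:
    """Concatenate datasets into one block-structured global-analysis target."""
    datasets = list(datasets)
    if not datasets:
        raise ValueError("nothing to augment")
    basis = datasets[0].components
    for ds in datasets[1:]:
        if ds.components != basis:
            raise ValueError(
                f"component basis mismatch: {ds.components} vs {basis}"
            )
    blocks = [b for ds in datasets for b in ds.blocks]
    kind = "noisy" if any(ds.kind == "noisy" for ds in datasets) else datasets[0].kind
    sd = max(ds.noise_sd for ds in datasets)
    return TitrationDataset(blocks, basis, kind=kind, noise_sd=sd)


# -- text I/O ----------------------------------------------------------------

def block_to_frame(block: TitrationBlock, components: Sequence[str]) -> pd.DataFrame:
    df = pd.DataFrame({"v_added": block.protocol.cumulative_volumes})
    for j, c in enumerate(components):
        df[f"tot_{c}"] = block.totals[:, j]
    df["pH"] = block.ph
    return df


def write_dataset(dataset: TitrationDataset, path) -> None:
    """Delimited text: per block, a two-line header then the data table."""
    with open(path, "w") as fh:
        for b in dataset.blocks:
            fh.write(f"# block label={b.protocol.label} kind={dataset.kind}\n")
            fh.write(
                f"# T={b.protocol.T} v0={b.protocol.v0} "
                f"noise_sd={dataset.noise_sd} seed={dataset.seed}\n"
            )
            block_to_frame(b, dataset.components).to_csv(fh, index=False)


def read_dataset(path) -> TitrationDataset:
    """Read a dataset written by :func:`write_dataset`."""
    with open(path) as fh:
        text = fh.read()
    chunks = [c for c in text.split("# block ")[1:]]
    blocks = []
    components: tuple = ()
    kind, noise_sd, seed = "measured", 0.0, None
    for chunk in chunks:
        lines = chunk.splitlines()
        head = dict(kv.split("=", 1) for kv in lines[0].split() if "=" in kv)
        meta = dict(
            kv.split("=", 1) for kv in lines[1].lstrip("# ").split() if "=" in kv
        )
        kind = head.get("kind", kind)
        noise_sd = float(meta.get("noise_sd", 0.0))
        seed = None if meta.get("seed") in (None, "None") else int(meta["seed"])
        df = pd.read_csv(io.StringIO("\n".join(lines[2:])))
        comp_cols = [c for c in df.columns if c.startswith("tot_")]
        components = tuple(c[4:] for c in comp_cols)
        v = df["v_added"].to_numpy()
        aliquots = tuple(np.diff(v))
        totals = df[comp_cols].to_numpy()
        v0 = float(meta["v0"])
        # invert the dilution formula at the final point for titrant totals
        initial = dict(zip(components, totals[0]))
        if len(v) > 1 and v[-1] > 0:
            titr = (totals[-1] * (v0 + v[-1]) - v0 * totals[0]) / v[-1]
        else:
            titr = np.zeros(len(components))
        proto = TitrationProtocol(
            head.get("label", "block"), float(meta["T"]), v0, initial,
            dict(zip(components, titr)), aliquots
        )
        blocks.append(TitrationBlock(proto, totals, df["pH"].to_numpy()))
    return TitrationDataset(blocks, components, kind=kind, noise_sd=noise_sd, seed=seed)


def read_protocol(path) -> TitrationProtocol:
    """Read a YAML protocol file.

    Schema: ``label``, ``T``, ``v0``, ``initial`` (mapping), ``titrant``
    (mapping), and either ``aliquots`` (list of litres) or ``n``/``vstep``.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return protocol_from_dict(doc)


def protocol_from_dict(doc: Mapping) -> TitrationProtocol:
    if "aliquots" in doc:
        aliquots = tuple(float(a) for a in doc["aliquots"])
    else:
        aliquots = (float(doc["vstep"]),) * int(doc["n"])
    return TitrationProtocol(
        label=str(doc.get("label", "titration")),
        T=float(doc["T"]),
        v0=float(doc.get("v0", 0.01)),
        initial_totals={str(k): float(v) for k, v in (doc.get("initial") or {}).items()},
        titrant_totals={str(k): float(v) for k, v in (doc.get("titrant") or {}).items()},
        aliquots=aliquots,
    )
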