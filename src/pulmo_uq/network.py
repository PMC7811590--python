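"""Arterial network representation, I/O, synthesis and Windkessel nominals.

A pulmonary arterial tree is a directed binary tree of straight vessel
segments.  Each terminal vessel carries a three-element Windkessel (RCR)
boundary condition whose *nominal* parameters are computed from the mean
haemodynamic state via Poiseuille resistances, and later adjusted by three
global scaling factors (psi1, psi2, c) shared by all terminals.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constants import PhysicalConstants
from .exceptions import (
    ConfigurationError,
    DomainError,
    NetworkParseError,
    NetworkValidationError,
)

__all__ = [
    "Vessel",
    "VesselNetwork",
    "NominalWindkessel",
    "ScalingFactors",
    "read_network",
    "write_network",
    "generate_tree",
    "nominal_windkessel",
    "apply_scalings",
    "poiseuille_resistance",
]

_A0_RTOL = 1e-12


@dataclass(frozen=True)
class Vessel:
    """A straight vessel segment.

    Attributes
    ----------
    id : int
        1-based integer label (file order).
    parent_id : int | None
        Label of the parent vessel; ``None`` marks the root.
    L : float
        Length, cm.
    r0 : float
        Unstressed radius, cm.
    terminal : bool
        True iff the vessel has no daughters (carries a Windkessel outlet).
    """

    id: int
    parent_id: int | None
    L: float
    r0: float
    terminal: bool

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise NetworkValidationError(f"vessel {self.id}: L must be > 0")
        if self.r0 <= 0:
            raise NetworkValidationError(f"vessel {self.id}: r0 must be > 0")

    @property
    def A0(self) -> float:
        """Unstressed cross-sectional area pi*r0^2, cm^2."""
        return math.pi * self.r0 ** 2


class VesselNetwork:
    """Directed binary tree of vessels.

    Invariants enforced at construction: exactly one root, every non-root
    has an existing parent, every internal vessel has exactly two daughters,
    and ``terminal`` flags are consistent with the topology.
    """

    def __init__(self, vessels: Iterable[Vessel]):
        vessels = list(vessels)
        ids = [v.id for v in vessels]
        if len(set(ids)) != len(ids):
            raise NetworkValidationError("duplicate vessel ids")
        self._by_id: dict[int, Vessel] = {v.id: v for v in vessels}
        roots = [v for v in vessels if v.parent_id is None]
        if len(roots) != 1:
            raise NetworkValidationError(
                f"network must have exactly one root, found {len(roots)}"
            )
        self.root: Vessel = roots[0]
        children: dict[int, list[int]] = {v.id: [] for v in vessels}
        for v in vessels:
            if v.parent_id is None:
                continue
            if v.parent_id not in self._by_id:
                raise NetworkValidationError(
                    f"vessel {v.id} lists nonexistent parent {v.parent_id}"
                )
            children[v.parent_id].append(v.id)
        # daughters ordered by id (junction assembly tie-break)
        self.children: dict[int, list[int]] = {
            k: sorted(c) for k, c in children.items()
        }
        for v in vessels:
            ndaughters = len(self.children[v.id])
            if v.terminal and ndaughters != 0:
                raise NetworkValidationError(
                    f"vessel {v.id} flagged terminal but has daughters"
                )
            if not v.terminal and ndaughters != 2:
                raise NetworkValidationError(
                    f"internal vessel {v.id} must have exactly 2 daughters, "
                    f"found {ndaughters}"
                )
        self._check_acyclic()
        self.vessels: list[Vessel] = vessels
        self.junctions: list[tuple[int, int, int]] = [
            (v.id, *self.children[v.id]) for v in vessels if not v.terminal
        ]

    def _check_acyclic(self) -> None:
        for v in self._by_id.values():
            seen = set()
            cur = v
            while cur.parent_id is not None:
                if cur.id in seen:
                    raise NetworkValidationError("network contains a cycle")
                seen.add(cur.id)
                cur = self._by_id[cur.parent_id]

    def __len__(self) -> int:
        return len(self.vessels)

    def __getitem__(self, vessel_id: int) -> Vessel:
        return self._by_id[vessel_id]

    def __contains__(self, vessel_id: int) -> bool:
        return vessel_id in self._by_id

    @property
    def terminal_vessels(self) -> list[Vessel]:
        return [v for v in self.vessels if v.terminal]

    @property
    def n_terminal(self) -> int:
        return len(self.terminal_vessels)

    def path_to_root(self, vessel_id: int) -> list[int]:
        """Vessel ids from the root down to ``vessel_id`` (inclusive)."""
        path = []
        cur = self._by_id[vessel_id]
        while True:
            path.append(cur.id)
            if cur.parent_id is None:
                break
            cur = self._by_id[cur.parent_id]
        return path[::-1]

    def edges(self) -> list[tuple[int, int]]:
        """Parent -> child edges (both orderings of each junction)."""
        return [
            (v.parent_id, v.id) for v in self.vessels if v.parent_id is not None
        ]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VesselNetwork):
            return NotImplemented
        return self.vessels == other.vessels

    def __repr__(self) -> str:
        return (
            f"VesselNetwork(n={len(self)}, terminals={self.n_terminal}, "
            f"root={self.root.id})"
        )


@dataclass
class NominalWindkessel:
    """Nominal RCR parameters per terminal vessel (cgs units).

    ``R1``/``R2`` in g ml^-1 cm^-1 s^-1 (= g cm^-4 s^-1), ``C`` in
    cm^4 s^2 g^-1 (dimensional reciprocal of the printed form).
    """

    terminal_ids: list[int]
    R1: np.ndarray
    R2: np.ndarray
    C: np.ndarray

    def __post_init__(self) -> None:
        self.R1 = np.asarray(self.R1, dtype=float)
        self.R2 = np.asarray(self.R2, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        if not (
            len(self.terminal_ids) == self.R1.size == self.R2.size == self.C.size
        ):
            raise ConfigurationError("Windkessel arrays must share one length")
        if np.any(self.R1 <= 0) or np.any(self.R2 <= 0) or np.any(self.C <= 0):
            raise ConfigurationError("Windkessel parameters must be positive")


@dataclass(frozen=True)
class ScalingFactors:
    """Global Windkessel scaling factors (dimensionless), shared by all outlets."""

    psi1: float = 1.0
    psi2: float = 1.0
    c: float = 1.0
    bounds: tuple[float, float] = (0.05, 2.50)

    def __post_init__(self) -> None:
        lo, hi = self.bounds
        for name in ("psi1", "psi2", "c"):
            val = getattr(self, name)
            if not (lo <= val <= hi):
                raise DomainError(
                    f"scaling factor {name}={val} outside bounds ({lo}, {hi})"
                )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["id", "parent_id", "length_cm", "r0_cm", "terminal"]


def _vessel_from_record(rec: dict, where: str) -> Vessel:
    try:
        vid = int(rec["id"])
        parent = rec.get("parent_id")
        if parent is None or (isinstance(parent, float) and math.isnan(parent)) \
                or parent == "":
            parent_id = None
        else:
            parent_id = int(parent)
        term = rec["terminal"]
        if isinstance(term, str):
            term = term.strip().lower() in ("1", "true", "yes")
        return Vessel(
            id=vid,
            parent_id=parent_id,
            L=float(rec["length_cm"]),
            r0=float(rec["r0_cm"]),
            terminal=bool(term),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise NetworkParseError(f"malformed network record at {where}: {rec!r}") \
            from exc


def read_network(path: str | Path) -> VesselNetwork:
    """Read a vessel network from CSV or JSON.

    CSV schema: header ``id,parent_id,length_cm,r0_cm,terminal`` with an empty
    ``parent_id`` for the root.  A JSON file holds an equivalent list of
    records (optionally under a top-level ``"vessels"`` key).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            doc = json.load(fh)
        records = doc["vessels"] if isinstance(doc, dict) else doc
        vessels = [
            _vessel_from_record(rec, f"{path.name}#{i}")
            for i, rec in enumerate(records)
        ]
    else:
        try:
            frame = pd.read_csv(path)
        except Exception as exc:  # malformed CSV
            raise NetworkParseError(f"cannot parse {path.name}: {exc}") from exc
        missing = set(_CSV_COLUMNS) - set(frame.columns)
        if missing:
            raise NetworkParseError(
                f"{path.name} missing columns {sorted(missing)}"
            )
        vessels = [
            _vessel_from_record(rec, f"{path.name}:row {i + 2}")
            for i, rec in enumerate(frame.to_dict("records"))
        ]
    return VesselNetwork(vessels)


def write_network(network: VesselNetwork, path: str | Path) -> None:
    """Write a network to CSV or JSON (chosen by extension); lossless round-trip."""
    path = Path(path)
    records = [
        {
            "id": v.id,
            "parent_id": v.parent_id,
            "length_cm": v.L,
            "r0_cm": v.r0,
            "terminal": v.terminal,
        }
        for v in network.vessels
    ]
    if path.suffix.lower() == ".json":
        with open(path, "w") as fh:
            json.dump({"vessels": records}, fh, indent=1)
    else:
        frame = pd.DataFrame(records, columns=_CSV_COLUMNS)
        frame["parent_id"] = frame["parent_id"].astype("Int64")
        frame.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Synthesis
# ---------------------------------------------------------------------------

def generate_tree(
    n_terminal: int,
    root_radius: float = 0.047,
    radius_ratio: float = 0.79,
    length_radius_ratio: float = 10.0,
    seed: int = 0,
    asymmetry: float = 0.06,
) -> VesselNetwork:
    """Synthesize a binary arterial tree with ``n_terminal`` leaves.

    Daughter radii are ``parent * radius_ratio`` perturbed by a small seeded
    left/right asymmetry, so the two lungs receive unequal flow, and vessel
    lengths follow ``L = length_radius_ratio * r0``.  The construction is a
    stand-in for segmented micro-CT geometry and is deterministic for a
    fixed seed.
    """
    if n_terminal < 2:
        raise DomainError("n_terminal must be >= 2")
    if not (0 < radius_ratio <= 1):
        raise DomainError("radius_ratio must lie in (0, 1]")
    if length_radius_ratio <= 0:
        raise DomainError("length_radius_ratio must be > 0")
    rng = np.random.default_rng(seed)
    vessels: list[Vessel] = []
    counter = iter(range(1, 2 * n_terminal))

    def build(n_leaves: int, r0: float, parent_id: int | None) -> None:
        vid = next(counter)
        terminal = n_leaves == 1
        vessels.append(
            Vessel(
                id=vid,
                parent_id=parent_id,
                L=length_radius_ratio * r0,
                r0=r0,
                terminal=terminal,
            )
        )
        if terminal:
            return
        n_left = (n_leaves + 1) // 2
        n_right = n_leaves - n_left
        jitter = asymmetry * rng.uniform(-1.0, 1.0)
        build(n_left, r0 * radius_ratio * (1.0 + jitter), vid)
        build(n_right, r0 * radius_ratio * (1.0 - jitter), vid)

    build(n_terminal, root_radius, None)
    return VesselNetwork(vessels)


# ---------------------------------------------------------------------------
# Nominal Windkessel parameters
# ---------------------------------------------------------------------------

def poiseuille_resistance(
    L: float, r0: float, mu: float
) -> float:
    """Poiseuille resistance 8*mu*L/(pi*r0^4) of a straight segment (cgs)."""
    return 8.0 * mu * L / (math.pi * r0 ** 4)


def nominal_windkessel(
    network: VesselNetwork,
    mean_flow: float,
    mean_pressure: float,
    proximal_fraction: float = 0.2,
    tau: float = 0.025,
    blood: PhysicalConstants | None = None,
) -> NominalWindkessel:
    """Compute nominal RCR parameters for every terminal vessel.

    The total resistance ``R_tot = conv * mean_pressure / mean_flow`` (cgs)
    is distributed over root-to-leaf branches inversely proportional to the
    terminal ``r0^4`` (Poiseuille weighting); the Poiseuille resistance of
    each leaf's root-to-leaf path is subtracted from its branch so that the
    parallel combination of (path + terminal RCR) reproduces
    ``mean_pressure / mean_flow`` exactly.  The terminal resistance is split
    ``R1 = proximal_fraction * R0`` / ``R2 = (1 - proximal_fraction) * R0``
    and the compliance set by the exponential decay time ``C = tau / R2``.

    Parameters
    ----------
    mean_flow : float
        Cycle-averaged inflow, ml s^-1.
    mean_pressure : float
        Target cycle-averaged root pressure, mmHg.
    proximal_fraction : float
        Fraction of each terminal resistance placed proximally (R1).
    tau : float
        Windkessel decay time R2*C, s.
    """
    blood = blood or PhysicalConstants()
    if mean_flow <= 0 or mean_pressure <= 0:
        raise ConfigurationError("mean_flow and mean_pressure must be positive")
    if not (0 < proximal_fraction < 1):
        raise ConfigurationError("proximal_fraction must lie in (0, 1)")
    if tau <= 0:
        raise ConfigurationError("tau must be positive")
    R_tot = blood.conv * mean_pressure / mean_flow
    terminals = network.terminal_vessels
    weights = np.array([v.r0 ** 4 for v in terminals])
    W = weights.sum()
    ids, R1s, R2s, Cs = [], [], [], []
    for v, w in zip(terminals, weights):
        path = sum(
            poiseuille_resistance(network[i].L, network[i].r0, blood.mu)
            for i in network.path_to_root(v.id)
        )
        R_branch = R_tot * W / w
        R0 = R_branch - path
        if R0 <= 0:
            raise ConfigurationError(
                f"network Poiseuille resistance on the path to vessel {v.id} "
                f"({path:.3g}) meets or exceeds its branch target "
                f"({R_branch:.3g}); mean_pressure/mean_flow too small"
            )
        ids.append(v.id)
        R1s.append(proximal_fraction * R0)
        R2s.append((1.0 - proximal_fraction) * R0)
        Cs.append(tau / ((1.0 - proximal_fraction) * R0))
    return NominalWindkessel(ids, np.array(R1s), np.array(R2s), np.array(Cs))


def apply_scalings(
    nominal: NominalWindkessel, s: ScalingFactors
) -> NominalWindkessel:
    """Scale nominal RCR values: R1j = psi1*R01j, R2j = psi2*R02j, Cj = c*C0j."""
    R1 = s.psi1 * nominal.R1
    R2 = s.psi2 * nominal.R2
    C = s.c * nominal.C
    if np.any(R1 <= 0) or np.any(R2 <= 0) or np.any(C <= 0):
        raise DomainError("scaled Windkessel parameters must remain positive")
    return NominalWindkessel(list(nominal.terminal_ids), R1, R2, C)
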