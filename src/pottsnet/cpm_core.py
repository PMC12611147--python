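"""Stochastic Cellular-Potts (Glazier-Graner-Hogeweg) engine on a periodic lattice.

Each cell is a set of lattice sites sharing an integer id (0 = medium).  Dynamics
proceed by Metropolis pixel-copy attempts: a random site may copy its id onto a
random lattice neighbor, accepted with the Boltzmann rule
``exp(-max(0, dH / H'))`` where ``dH`` is the change in the effective energy

    H = sum_neighbors J_{tau(si),tau(sj)} (1 - delta_{si,sj})
      + sum_cells lambda_vol (V - V_target)^2 + lambda_surf (S - S_target)^2

plus a per-copy saturated chemotaxis bias toward high concentrations of a
secreted diffusive field.  One Monte-Carlo step (MCS) is ``width * height``
copy attempts followed by one chemical-field update.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np
from numba import njit

__all__ = [
    "ModelParams",
    "LatticeState",
    "CopyAttempt",
    "total_energy",
    "delta_energy",
    "acceptance_probability",
    "run_mcs",
]

# 4-connected (von Neumann) offsets: copy candidates and surface faces.
OFFSETS_ORDER1 = np.array([(0, 1), (0, -1), (1, 0), (-1, 0)], dtype=np.int64)
# 8-connected (Moore) offsets: default contact-energy neighborhood.
OFFSETS_ORDER2 = np.array(
    [(0, 1), (0, -1), (1, 0), (-1, 0), (1, 1), (1, -1), (-1, 1), (-1, -1)],
    dtype=np.int64,
)


def contact_offsets(order: int) -> np.ndarray:
    """Neighbor offsets for the contact-energy sum (1 = von Neumann, 2 = Moore)."""
    if order == 1:
        return OFFSETS_ORDER1
    if order == 2:
        return OFFSETS_ORDER2
    raise ValueError(f"contact_neighbor_order must be 1 or 2, got {order}")


@dataclass
class ModelParams:
    """Every parameter of the vasculogenesis model.

    Energy parameters default to the published parameterization of the model:
    volume constraint 5 toward 50 sites, surface constraint 1 toward 16.8
    faces, contact energies J(cell,medium)=8.2 and J(cell,cell)=6, saturated
    chemotaxis with strength 2000 and saturation 0.5, field decay 0.6 per MCS,
    and Potts temperature 8.  The diffusion constant and secretion rate have
    no published values; the defaults here were calibrated to reproduce the
    network morphology (see docs/calibration.md).
    """

    lambda_volume: float = 5.0        # energy / site^2
    V_target: float = 50.0            # sites
    lambda_surface: float = 1.0       # energy / face^2
    S_target: float = 16.8            # faces
    J_cell_medium: float = 8.2        # energy / contact face
    J_cell_cell: float = 6.0          # energy / contact face
    lambda_chemotaxis: float = 2000.0  # energy
    s: float = 0.5                    # 1 / concentration (chemotaxis saturation)
    k: float = 0.6                    # 1 / MCS (field decay)
    D: float = 8.0                    # sites^2 / MCS (field diffusion; calibrated)
    secretion_rate: float = 100.0     # concentration / MCS at cell-occupied sites (calibrated)
    temperature_Hprime: float = 8.0   # energy (Boltzmann scale H')
    lattice_size: int = 256           # sites per dimension
    n_cells_initial: int = 1000
    cell_block_size: int = 5          # side of the square block each cell starts as
    contact_neighbor_order: int = 2   # neighborhood for the contact-energy sum
    chemotaxis_mode: str = "push_pull"  # "push_pull": advance rewarded, displacement
                                        # penalized; "extension_only": bias only when a
                                        # cell advances (retraction is chemotaxis-blind)
    pde_substeps: int = 34            # explicit-Euler substeps per MCS (stable for D=8)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        nonneg = {
            "lambda_volume": self.lambda_volume,
            "lambda_surface": self.lambda_surface,
            "lambda_chemotaxis": self.lambda_chemotaxis,
            "s": self.s,
            "k": self.k,
            "D": self.D,
            "secretion_rate": self.secretion_rate,
        }
        for name, value in nonneg.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if self.temperature_Hprime <= 0:
            raise ValueError("temperature_Hprime must be > 0")
        if self.V_target <= 0 or self.S_target <= 0:
            raise ValueError("V_target and S_target must be > 0")
        if self.lattice_size < 8:
            raise ValueError("lattice_size must be >= 8")
        if self.contact_neighbor_order not in (1, 2):
            raise ValueError("contact_neighbor_order must be 1 or 2")
        if self.chemotaxis_mode not in ("push_pull", "extension_only"):
            raise ValueError("chemotaxis_mode must be 'push_pull' or 'extension_only'")
        if self.pde_substeps < 1:
            raise ValueError("pde_substeps must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d)


@dataclass
class CopyAttempt:
    """A proposed pixel copy: ``source_site`` overwrites ``dest_site``.

    The two sites must be 4-neighbors under periodic wraparound.
    """

    source_site: tuple
    dest_site: tuple
    source_id: int
    dest_id: int


class LatticeState:
    """Simulation state: cell-id lattice, chemical field, cached cell statistics.

    ``volumes[i]`` / ``surfaces[i]`` cache the site count and 4-neighbor
    boundary-face count of cell ``i`` (index 0, the medium, is unused).  The
    caches are maintained incrementally by the sweep kernel and can always be
    recomputed from the lattice (see :meth:`validate`).
    """

    def __init__(
        self,
        cell_id_lattice: np.ndarray,
        field: np.ndarray,
        mcs: int = 0,
        type_label: str = "vessel",
    ):
        lattice = np.ascontiguousarray(cell_id_lattice, dtype=np.int32)
        if lattice.ndim != 2:
            raise ValueError("cell_id_lattice must be 2D")
        if field.shape != lattice.shape:
            raise ValueError("field shape must match lattice shape")
        self.cell_id_lattice = lattice
        self.field = np.ascontiguousarray(field, dtype=np.float64)
        self.mcs = int(mcs)
        self.type_label = type_label
        n_ids = int(lattice.max()) + 1 if lattice.size else 1
        self.volumes = recount_volumes(lattice, n_ids)
        self.surfaces = recount_surfaces(lattice, n_ids)

    @property
    def shape(self) -> tuple:
        return self.cell_id_lattice.shape

    @property
    def cells(self) -> dict:
        """Table of live cells: id -> {type_label, current_volume, current_surface}."""
        out = {}
        for cid in range(1, len(self.volumes)):
            if self.volumes[cid] > 0:
                out[cid] = {
                    "type_label": self.type_label,
                    "current_volume": int(self.volumes[cid]),
                    "current_surface": int(self.surfaces[cid]),
                }
        return out

    def vessel_mask(self) -> np.ndarray:
        return (self.cell_id_lattice > 0).astype(np.uint8)

    def copy(self) -> "LatticeState":
        return LatticeState(
            self.cell_id_lattice.copy(), self.field.copy(), self.mcs, self.type_label
        )

    def validate(self) -> None:
        """Check all state invariants; raise ``ValueError`` on any violation."""
        lattice = self.cell_id_lattice
        if lattice.min() < 0:
            raise ValueError("negative cell id on lattice")
        if not np.all(np.isfinite(self.field)):
            raise ValueError("non-finite field values")
        if self.field.min() < 0:
            raise ValueError("negative field values")
        n_ids = len(self.volumes)
        if lattice.max() >= n_ids:
            raise ValueError("lattice id outside bookkeeping range")
        vol = recount_volumes(lattice, n_ids)
        if not np.array_equal(vol, self.volumes):
            raise ValueError("cached volumes inconsistent with lattice recount")
        surf = recount_surfaces(lattice, n_ids)
        if not np.array_equal(surf, self.surfaces):
            raise ValueError("cached surfaces inconsistent with lattice recount")


def recount_volumes(lattice: np.ndarray, n_ids: int) -> np.ndarray:
    """Site count per id, recomputed from scratch (index 0 = medium, unused)."""
    counts = np.bincount(lattice.ravel(), minlength=n_ids).astype(np.int64)
    counts[0] = 0
    return counts


def recount_surfaces(lattice: np.ndarray, n_ids: int) -> np.ndarray:
    """4-neighbor boundary-face count per cell, recomputed from scratch.

    A face between sites of two different cells counts toward the surface of
    both; a face against the medium counts only for the cell.
    """
    surf = np.zeros(n_ids, dtype=np.int64)
    for axis, shift in ((0, 1), (1, 1)):
        other = np.roll(lattice, -shift, axis=axis)
        diff = lattice != other
        a = lattice[diff]
        b = other[diff]
        surf += np.bincount(a[a > 0], minlength=n_ids)
        surf += np.bincount(b[b > 0], minlength=n_ids)
    surf[0] = 0
    return surf


# ---------------------------------------------------------------------------
# Energies
# ---------------------------------------------------------------------------

def total_energy(state: LatticeState, params: ModelParams) -> float:
    """Brute-force total effective energy (contact + volume + surface terms).

    The chemotaxis term is path-dependent (it involves a copy's source and
    destination) and therefore contributes only to per-attempt energy changes,
    never to the static total.  Used as the reference oracle for the
    incremental ``delta_energy``.
    """
    state.validate()
    lattice = state.cell_id_lattice
    offs = contact_offsets(params.contact_neighbor_order)
    # Half-neighborhood so each unordered pair is counted once.
    half = _half_offsets(offs)
    energy = 0.0
    for dr, dc in half:
        other = np.roll(np.roll(lattice, -dr, axis=0), -dc, axis=1)
        diff = lattice != other
        touching_medium = diff & ((lattice == 0) | (other == 0))
        n_cm = int(touching_medium.sum())
        n_cc = int(diff.sum()) - n_cm
        energy += params.J_cell_medium * n_cm + params.J_cell_cell * n_cc
    vol = state.volumes
    surf = state.surfaces
    alive = vol > 0
    energy += params.lambda_volume * float(((vol[alive] - params.V_target) ** 2).sum())
    energy += params.lambda_surface * float(((surf[alive] - params.S_target) ** 2).sum())
    return energy


def _half_offsets(offs: np.ndarray) -> list:
    """Keep one of each +/- offset pair so neighbor pairs are counted once."""
    seen = set()
    half = []
    for dr, dc in offs.tolist():
        if (-dr, -dc) in seen:
            continue
        seen.add((dr, dc))
        half.append((dr, dc))
    return half


@njit(cache=True)
def _delta_H(
    lattice,
    field,
    volumes,
    surfaces,
    r,
    c,
    nr,
    nc,
    lam_v,
    V_t,
    lam_s,
    S_t,
    J_cm,
    J_cc,
    lam_chem,
    s_sat,
    chemo_extension_only,
    contact_offs,
):
    """Incremental dH for copying the id at (nr, nc) onto (r, c).

    Returns (dH, dS_source_cell, dS_dest_cell); the surface deltas are reused
    by the sweep kernel when the copy is accepted.
    """
    H, W = lattice.shape
    src = lattice[nr, nc]
    dst = lattice[r, c]
    dH = 0.0

    # Contact term over the configured neighborhood of the destination site.
    for i in range(contact_offs.shape[0]):
        mr = (r + contact_offs[i, 0]) % H
        mc = (c + contact_offs[i, 1]) % W
        m = lattice[mr, mc]
        if m != src:
            dH += J_cm if (m == 0 or src == 0) else J_cc
        if m != dst:
            dH -= J_cm if (m == 0 or dst == 0) else J_cc

    # Volume constraint for the growing (src) and shrinking (dst) cells.
    if src > 0:
        v = volumes[src]
        dH += lam_v * ((v + 1 - V_t) ** 2 - (v - V_t) ** 2)
    if dst > 0:
        v = volumes[dst]
        dH += lam_v * ((v - 1 - V_t) ** 2 - (v - V_t) ** 2)

    # Surface constraint: only the two involved cells change surface.
    n_src = 0
    n_dst = 0
    for i in range(4):
        mr = (r + _OFF4[i, 0]) % H
        mc = (c + _OFF4[i, 1]) % W
        m = lattice[mr, mc]
        if m == src:
            n_src += 1
        if m == dst:
            n_dst += 1
    dS_src = 4 - 2 * n_src
    dS_dst = 2 * n_dst - 4
    if src > 0:
        sst = surfaces[src]
        dH += lam_s * ((sst + dS_src - S_t) ** 2 - (sst - S_t) ** 2)
    if dst > 0:
        sst = surfaces[dst]
        dH += lam_s * ((sst + dS_dst - S_t) ** 2 - (sst - S_t) ** 2)

    # Saturated chemotaxis, per copy.  A cell advancing into the destination
    # is rewarded for moving up-gradient; a cell being displaced by medium is
    # penalized for retreating from high concentration.
    if lam_chem != 0.0:
        cd = field[r, c]
        cs = field[nr, nc]
        term = lam_chem * (cd / (s_sat * cd + 1.0) - cs / (s_sat * cs + 1.0))
        if src > 0:
            dH -= term
        elif not chemo_extension_only:
            dH += term

    return dH, dS_src, dS_dst


_OFF4 = OFFSETS_ORDER1


def delta_energy(
    state: LatticeState, params: ModelParams, attempt: CopyAttempt
) -> float:
    """Incremental energy change dH of a pixel-copy attempt.

    Exactly the quantity the sweep kernel scores: local contact change, volume
    and surface change for the two involved cells, and the per-copy saturated
    chemotaxis bias.  With chemotaxis off it equals
    ``total_energy(after) - total_energy(before)``.
    """
    (sr, sc), (dr, dc) = attempt.source_site, attempt.dest_site
    H, W = state.shape
    if (sr, sc) == (dr, dc):
        raise ValueError("source and destination sites must differ")
    if not _are_neighbors(sr, sc, dr, dc, H, W):
        raise ValueError("sites must be 4-neighbors under periodic wraparound")
    src = int(state.cell_id_lattice[sr, sc])
    dst = int(state.cell_id_lattice[dr, dc])
    if src != attempt.source_id or dst != attempt.dest_id:
        raise ValueError("attempt ids inconsistent with lattice")
    if src == dst:
        raise ValueError("same-cell attempts are no-ops and are never scored")
    dH, _, _ = _delta_H(
        state.cell_id_lattice,
        state.field,
        state.volumes,
        state.surfaces,
        dr,
        dc,
        sr,
        sc,
        params.lambda_volume,
        params.V_target,
        params.lambda_surface,
        params.S_target,
        params.J_cell_medium,
        params.J_cell_cell,
        params.lambda_chemotaxis,
        params.s,
        params.chemotaxis_mode == "extension_only",
        contact_offsets(params.contact_neighbor_order),
    )
    return float(dH)


def _are_neighbors(r0, c0, r1, c1, H, W):
    dr = min((r0 - r1) % H, (r1 - r0) % H)
    dc = min((c0 - c1) % W, (c1 - c0) % W)
    return dr + dc == 1


def acceptance_probability(delta_H: float, temperature_Hprime: float) -> float:
    """Boltzmann acceptance ``exp(-max(0, dH / H'))``; 1 for energy-lowering moves."""
    if temperature_Hprime <= 0:
        raise ValueError("temperature_Hprime must be > 0")
    return math.exp(-max(0.0, delta_H / temperature_Hprime))


# ---------------------------------------------------------------------------
# Monte-Carlo sweeps
# ---------------------------------------------------------------------------

@njit(cache=True)
def _seed_kernel(seed):
    np.random.seed(seed)


@njit(cache=True)
def _sweep(
    lattice,
    field,
    volumes,
    surfaces,
    lam_v,
    V_t,
    lam_s,
    S_t,
    J_cm,
    J_cc,
    lam_chem,
    s_sat,
    chemo_extension_only,
    temperature,
    contact_offs,
):
    """One MCS of lattice.size pixel-copy attempts; returns accepted count."""
    H, W = lattice.shape
    n_attempts = H * W
    accepted = 0
    for _ in range(n_attempts):
        r = np.random.randint(0, H)
        c = np.random.randint(0, W)
        i = np.random.randint(0, 4)
        nr = (r + _OFF4[i, 0]) % H
        nc = (c + _OFF4[i, 1]) % W
        src = lattice[nr, nc]
        dst = lattice[r, c]
        if src == dst:
            continue
        dH, dS_src, dS_dst = _delta_H(
            lattice, field, volumes, surfaces, r, c, nr, nc,
            lam_v, V_t, lam_s, S_t, J_cm, J_cc, lam_chem, s_sat,
            chemo_extension_only, contact_offs,
        )
        if dH > 0.0:
            if np.random.random() >= np.exp(-dH / temperature):
                continue
        lattice[r, c] = src
        if src > 0:
            volumes[src] += 1
            surfaces[src] += dS_src
        if dst > 0:
            volumes[dst] -= 1
            surfaces[dst] += dS_dst
        accepted += 1
    return accepted


def run_mcs(
    state: LatticeState,
    params: ModelParams,
    rng: Optional[np.random.Generator] = None,
    n_mcs: int = 1,
) -> LatticeState:
    """Advance the state by ``n_mcs`` Monte-Carlo steps in place.

    Each MCS performs ``lattice_size**2`` copy attempts (uniform random site,
    uniform random 4-neighbor as the copy source, Boltzmann acceptance) and
    then one chemical-field update with secretion at cell-occupied sites.
    Deterministic given the generator state.  Returns the same state object.
    """
    from .chemical_field import FieldUpdateConfig, step_field_fast

    if n_mcs < 0:
        raise ValueError("n_mcs must be >= 0")
    if n_mcs == 0:
        return state
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    _seed_kernel(int(rng.integers(0, 2**31 - 1)))
    cfg = FieldUpdateConfig(
        D=params.D,
        k=params.k,
        secretion_rate=params.secretion_rate,
        n_substeps=params.pde_substeps,
    )
    offs = contact_offsets(params.contact_neighbor_order)
    for _ in range(n_mcs):
        accepted = _sweep(
            state.cell_id_lattice,
            state.field,
            state.volumes,
            state.surfaces,
            params.lambda_volume,
            params.V_target,
            params.lambda_surface,
            params.S_target,
            params.J_cell_medium,
            params.J_cell_cell,
            params.lambda_chemotaxis,
            params.s,
            params.chemotaxis_mode == "extension_only",
            params.temperature_Hprime,
            offs,
        )
        state.last_acceptance_rate = accepted / state.cell_id_lattice.size
        state.field = step_field_fast(state.field, state.cell_id_lattice > 0, cfg)
        state.mcs += 1
    return state
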