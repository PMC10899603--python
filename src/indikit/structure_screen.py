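"""Structure-based stabilization screens.

Three design routes operate on a protein coordinate model:

* **Disulfide scanning** — enumerate residue pairs whose backbone geometry can
  accommodate an engineered cystine.  Candidate Sgamma positions are modeled
  from each Cbeta on a chi1 grid and accepted when some chi1 pair yields an
  Sgamma-Sgamma distance near the 2.05 angstrom bond length with a chi3
  dihedral in the favorable window around 87 degrees.  This is a geometric
  criteria family of our own; no parity with any particular published scanner
  is implied.
* **Flexible-segment detection** — z-normalized Calpha B-factors, smoothed by
  a sliding window, flag loops that are disordered in the crystal and hence
  candidates for loop grafting.
* **Loop grafting** — donor loops from homolog structures are screened by
  rigid superposition (Kabsch) of the anchor residues flanking the target
  loop; only donors whose loop is strictly shorter qualify.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .errors import (
    DegenerateBFactorError,
    DegenerateGeometryError,
    EmptyStructureError,
    InputError,
    StructureParseError,
)

# ---------------------------------------------------------------------------
# Geometry primitives
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    return v / n


def dihedral_angle(p0, p1, p2, p3) -> np.ndarray | float:
    """Signed dihedral (degrees, IUPAC convention); broadcasts over points."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = _unit(p2 - p1)
    b2 = p3 - p2
    v = b0 - np.sum(b0 * b1, axis=-1, keepdims=True) * b1
    w = b2 - np.sum(b2 * b1, axis=-1, keepdims=True) * b1
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1, v) * w, axis=-1)
    out = np.degrees(np.arctan2(y, x))
    return float(out) if out.ndim == 0 else out


def bond_angle(p0, p1, p2) -> float:
    a = _unit(np.asarray(p0, float) - p1)
    b = _unit(np.asarray(p2, float) - p1)
    return float(np.degrees(np.arccos(np.clip(np.dot(a, b), -1.0, 1.0))))


def place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg) -> np.ndarray:
    """Place atom D given chain A-B-C, |CD|, angle B-C-D and dihedral A-B-C-D.

    ``dihedral_deg`` may be an array, in which case one position per value is
    returned (shape (n, 3)).
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = np.radians(angle_deg)
    dih = np.atleast_1d(np.radians(dihedral_deg))
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d = (-bond * np.cos(ang)) * bc \
        + (bond * np.sin(ang) * np.cos(dih))[:, None] * m \
        + (bond * np.sin(ang) * np.sin(dih))[:, None] * n
    out = c + d
    return out[0] if np.isscalar(dihedral_deg) or np.ndim(dihedral_deg) == 0 else out


def reconstruct_cb(n, ca, c) -> np.ndarray:
    """Ideal Cbeta from backbone N/Calpha/C (tetrahedral, 1.53 angstrom).

    Used for glycine so that Gly positions remain screenable.
    """
    n, ca, c = (np.asarray(p, dtype=float) for p in (n, ca, c))
    b = ca - n
    cv = c - ca
    a = np.cross(b, cv)
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * cv + ca


# ---------------------------------------------------------------------------
# Structure model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Residue:
    chain: str
    res_id: int
    icode: str
    res_name: str
    hetero: bool
    atoms: dict[str, int]  # atom name -> index into the parent arrays


@dataclass
class StructureModel:
    """A single coordinate model with B-factors and occupancies.

    Author residue numbering (with insertion codes) is preserved; alternate
    locations are already resolved to one conformer per atom.
    """

    chain: np.ndarray
    res_id: np.ndarray
    icode: np.ndarray
    res_name: np.ndarray
    atom_name: np.ndarray
    coord: np.ndarray
    b_factor: np.ndarray
    occupancy: np.ndarray
    hetero: np.ndarray
    model_id: int = 1

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coord)):
            raise StructureParseError("non-finite coordinates")

    def __len__(self) -> int:
        return len(self.atom_name)

    def residues(self) -> list[Residue]:
        """Residues in file order with name->index atom maps."""
        out: list[Residue] = []
        key = None
        for i in range(len(self)):
            k = (str(self.chain[i]), int(self.res_id[i]), str(self.icode[i]))
            if k != key:
                out.append(Residue(k[0], k[1], k[2], str(self.res_name[i]),
                                   bool(self.hetero[i]), {}))
                key = k
            out[-1].atoms.setdefault(str(self.atom_name[i]), i)
        return out

    def ca_lookup(self, chain: str | None = None) -> dict[int, np.ndarray]:
        """res_id -> Calpha coordinate for one chain (first chain if None)."""
        chains = [str(c) for c in dict.fromkeys(self.chain)]
        if chain is None:
            chain = chains[0]
        out = {}
        for r in self.residues():
            if r.chain == chain and "CA" in r.atoms and not r.hetero:
                out.setdefault(r.res_id, self.coord[r.atoms["CA"]])
        return out


def _prevalidate_pdb_text(path) -> None:
    """Cheap fixed-column check so parse errors carry a line number."""
    n_atom = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                if line.startswith("ATOM"):
                    n_atom += 1
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    try:
                        float(line[lo:hi])
                    except ValueError:
                        raise StructureParseError(
                            f"malformed coordinate field at line {lineno}: "
                            f"{line.rstrip()!r}"
                        ) from None
    if n_atom == 0:
        raise EmptyStructureError(f"no ATOM records in {path}")


def read_structure(path, model: int = 1) -> StructureModel:
    """Read one model from a PDB file.

    Alternate locations are resolved to the highest-occupancy conformer
    (label order on ties); HETATM records are retained but flagged.
    """
    from biotite.structure.io.pdb import PDBFile

    _prevalidate_pdb_text(path)
    try:
        pdb = PDBFile.read(str(path))
        arr = pdb.get_structure(model=model, altloc="occupancy",
                                extra_fields=["b_factor", "occupancy"])
    except Exception as exc:  # biotite raises several types
        raise StructureParseError(f"failed to parse {path}: {exc}") from exc
    return StructureModel(
        chain=np.asarray(arr.chain_id),
        res_id=np.asarray(arr.res_id),
        icode=np.asarray(arr.ins_code),
        res_name=np.asarray(arr.res_name),
        atom_name=np.asarray(arr.atom_name),
        coord=np.asarray(arr.coord, dtype=float),
        b_factor=np.asarray(arr.b_factor, dtype=float),
        occupancy=np.asarray(arr.occupancy, dtype=float),
        hetero=np.asarray(arr.hetero, dtype=bool),
        model_id=model,
    )


def write_structure(model: StructureModel, path) -> None:
    """Write the model as PDB text (coordinates at the format's 3 decimals)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = len(model)
    arr = struc.AtomArray(n)
    arr.chain_id = model.chain.astype("U4")
    arr.res_id = model.res_id.astype(int)
    arr.ins_code = model.icode.astype("U1")
    arr.res_name = model.res_name.astype("U5")
    arr.atom_name = model.atom_name.astype("U6")
    arr.coord = model.coord.astype(np.float32)
    arr.hetero = model.hetero.astype(bool)
    arr.set_annotation("b_factor", model.b_factor.astype(float))
    arr.set_annotation("occupancy", model.occupancy.astype(float))
    arr.set_annotation("element", np.array(
        [name.strip()[0] for name in model.atom_name], dtype="U2"))
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Disulfide scanning
# ---------------------------------------------------------------------------

#: Geometry constants shared with the synthetic-structure generator so that a
#: planted ideal pair is recovered with (near) zero strain.
CB_SG_BOND = 1.81          # angstrom
CA_CB_SG_ANGLE = 109.471   # degrees, tetrahedral
SS_BOND = 2.05             # angstrom, ideal Sgamma-Sgamma
CHI3_IDEAL = 87.0          # degrees


@dataclass(frozen=True)
class DisulfideGeometry:
    """Acceptance windows for the geometric disulfide scan."""

    ca_ca_max: float = 7.5
    cb_cb_min: float = 3.0
    cb_cb_max: float = 5.0
    ss_tol: float = 0.35        # |d(Sg,Sg) - 2.05| window
    chi3_min: float = 60.0
    chi3_max: float = 120.0
    chi3_scale: float = 30.0    # strain denominator for chi3
    chi1_step: float = 5.0      # grid resolution, degrees
    min_sep: int = 3            # minimum sequence separation, same chain


@dataclass(frozen=True)
class DisulfideCandidate:
    res_a: tuple[str, int]      # (chain, residue number)
    res_b: tuple[str, int]
    cb_cb_distance: float
    chi1_pair: tuple[float, float]
    sg_sg_distance: float
    chi3: float
    strain_score: float
    interchain: bool


def disulfide_strain(sg_distance: float, chi3: float,
                     geom: DisulfideGeometry = DisulfideGeometry()) -> float:
    """Dimensionless strain, 0 at ideal geometry (2.05 angstrom, |chi3| 87)."""
    return ((sg_distance - SS_BOND) / geom.ss_tol) ** 2 \
        + ((abs(chi3) - CHI3_IDEAL) / geom.chi3_scale) ** 2


def _within_windows(d: float, chi3: float, geom: DisulfideGeometry) -> bool:
    return (abs(d - SS_BOND) <= geom.ss_tol
            and geom.chi3_min <= abs(chi3) <= geom.chi3_max)


def _sg_grid(n, ca, cb, chi1_values) -> np.ndarray:
    return place_atom(n, ca, cb, CB_SG_BOND, CA_CB_SG_ANGLE, chi1_values)


def _pair_geometry(frame_a, frame_b, chi1_a, chi1_b):
    """Sgamma distance and chi3 for given chi1 values (scalars)."""
    sg_a = _sg_grid(*frame_a, np.array([chi1_a]))[0]
    sg_b = _sg_grid(*frame_b, np.array([chi1_b]))[0]
    d = float(np.linalg.norm(sg_a - sg_b))
    chi3 = float(dihedral_angle(frame_a[2], sg_a, sg_b, frame_b[2]))
    return d, chi3


def evaluate_pair(frame_a, frame_b, geom: DisulfideGeometry = DisulfideGeometry(),
                  refine: bool = True):
    """Scan chi1 x chi1 for one residue pair.

    ``frame_a``/``frame_b`` are (N, CA, CB) coordinate triples.  Returns
    ``None`` if no chi1 combination satisfies the windows, else a dict with
    the best (lowest-strain) geometry.  A local continuous refinement of the
    best grid point keeps the decision essentially resolution-independent.
    """
    chi1 = np.arange(-180.0, 180.0, geom.chi1_step)
    sg_a = _sg_grid(*frame_a, chi1)          # (n, 3)
    sg_b = _sg_grid(*frame_b, chi1)
    diff = sg_a[:, None, :] - sg_b[None, :, :]
    d = np.linalg.norm(diff, axis=-1)        # (n, n)
    cb_a = np.broadcast_to(frame_a[2], sg_a.shape)
    cb_b = np.broadcast_to(frame_b[2], sg_b.shape)
    chi3 = dihedral_angle(cb_a[:, None, :], sg_a[:, None, :],
                          sg_b[None, :, :], cb_b[None, :, :])
    strain = ((d - SS_BOND) / geom.ss_tol) ** 2 \
        + ((np.abs(chi3) - CHI3_IDEAL) / geom.chi3_scale) ** 2
    ok = (np.abs(d - SS_BOND) <= geom.ss_tol) \
        & (np.abs(chi3) >= geom.chi3_min) & (np.abs(chi3) <= geom.chi3_max)

    masked = np.where(ok, strain, np.inf)
    i, j = np.unravel_index(int(np.argmin(masked)), masked.shape)
    if not ok[i, j]:
        # fall back to the overall strain minimum as the refinement start
        i, j = np.unravel_index(int(np.argmin(strain)), strain.shape)
    best = dict(chi1_a=float(chi1[i]), chi1_b=float(chi1[j]),
                d=float(d[i, j]), chi3=float(chi3[i, j]),
                strain=float(strain[i, j]), accepted=bool(ok[i, j]))

    if refine:
        def objective(x):
            dd, c3 = _pair_geometry(frame_a, frame_b, x[0], x[1])
            return disulfide_strain(dd, c3, geom)

        res = minimize(objective, x0=[best["chi1_a"], best["chi1_b"]],
                       method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-10, "maxiter": 400})
        dd, c3 = _pair_geometry(frame_a, frame_b, res.x[0], res.x[1])
        if _within_windows(dd, c3, geom) and res.fun <= best["strain"]:
            best = dict(chi1_a=float(res.x[0]), chi1_b=float(res.x[1]),
                        d=dd, chi3=c3, strain=float(res.fun), accepted=True)
    return best if best["accepted"] else None


def scan_disulfides(structure: StructureModel,
                    geom: DisulfideGeometry = DisulfideGeometry(),
                    refine: bool = True) -> list[DisulfideCandidate]:
    """Enumerate residue pairs that could form a disulfide bridge.

    Pairs with sequence separation >= ``geom.min_sep`` (same chain) or on
    different chains pass a Calpha/Cbeta distance prefilter, then a chi1 x
    chi1 scan models both Sgamma atoms; see :func:`evaluate_pair` for the
    acceptance windows.  Proline is excluded as a partner; glycine Cbeta is
    reconstructed.  Results are sorted by ascending strain and are invariant
    to input atom order (canonical pair ordering).
    """
    usable = []
    for res in structure.residues():
        if res.hetero:
            continue
        if res.res_name == "PRO":
            continue
        if not all(a in res.atoms for a in ("N", "CA", "C")):
            warnings.warn(f"residue {res.chain}{res.res_id} missing backbone "
                          "atoms; skipped", stacklevel=2)
            continue
        n = structure.coord[res.atoms["N"]]
        ca = structure.coord[res.atoms["CA"]]
        c = structure.coord[res.atoms["C"]]
        cb = (structure.coord[res.atoms["CB"]] if "CB" in res.atoms
              else reconstruct_cb(n, ca, c))
        usable.append((res, n, ca, cb))
    usable.sort(key=lambda t: (t[0].chain, t[0].res_id, t[0].icode))

    if not usable:
        return []
    ca_all = np.array([u[2] for u in usable])
    cb_all = np.array([u[3] for u in usable])
    out: list[DisulfideCandidate] = []
    for i in range(len(usable)):
        res_i, n_i, ca_i, cb_i = usable[i]
        d_ca = np.linalg.norm(ca_all[i + 1:] - ca_all[i], axis=1)
        d_cb = np.linalg.norm(cb_all[i + 1:] - cb_all[i], axis=1)
        for off in np.nonzero((d_ca <= geom.ca_ca_max)
                              & (d_cb >= geom.cb_cb_min)
                              & (d_cb <= geom.cb_cb_max))[0]:
            j = i + 1 + int(off)
            res_j, n_j, ca_j, cb_j = usable[j]
            same_chain = res_i.chain == res_j.chain
            if same_chain and abs(res_i.res_id - res_j.res_id) < geom.min_sep:
                continue
            best = evaluate_pair((n_i, ca_i, cb_i), (n_j, ca_j, cb_j),
                                 geom, refine=refine)
            if best is None:
                continue
            out.append(DisulfideCandidate(
                res_a=(res_i.chain, res_i.res_id),
                res_b=(res_j.chain, res_j.res_id),
                cb_cb_distance=float(d_cb[off]),
                chi1_pair=(best["chi1_a"], best["chi1_b"]),
                sg_sg_distance=best["d"],
                chi3=best["chi3"],
                strain_score=best["strain"],
                interchain=not same_chain,
            ))
    out.sort(key=lambda c: c.strain_score)
    return out


# ---------------------------------------------------------------------------
# B-factor flexible segments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlexibleSegment:
    chain: str
    start: int
    end: int
    mean_z: float


def flexible_segments(structure: StructureModel, window: int = 5,
                      z_threshold: float = 1.0) -> list[FlexibleSegment]:
    """Flag high-B-factor segments per chain.

    Calpha B-factors are z-normalized over each chain (so the result is
    invariant under affine rescaling of all B-factors), smoothed with a
    centered ``window``-residue mean, and maximal runs above ``z_threshold``
    are merged into segments.  Segments never overlap and are sorted.
    """
    import pandas as pd

    segments: list[FlexibleSegment] = []
    residues = [r for r in structure.residues()
                if not r.hetero and "CA" in r.atoms]
    if not residues:
        raise InputError("no Calpha atoms in structure")
    all_b = np.array([structure.b_factor[r.atoms["CA"]] for r in residues])
    if np.ptp(all_b) == 0:
        raise DegenerateBFactorError("all Calpha B-factors equal")
    for chain in dict.fromkeys(r.chain for r in residues):
        rs = [r for r in residues if r.chain == chain]
        b = np.array([structure.b_factor[r.atoms["CA"]] for r in rs])
        if np.ptp(b) == 0:
            continue
        z = (b - b.mean()) / b.std()
        # full windows only: the smoothed value is undefined at the termini
        zs = pd.Series(z).rolling(window, center=True).mean().to_numpy()
        above = np.where(np.isnan(zs), False, zs > z_threshold)
        start = None
        for k in range(len(rs) + 1):
            if k < len(rs) and above[k]:
                if start is None:
                    start = k
            elif start is not None:
                segments.append(FlexibleSegment(
                    chain=chain, start=rs[start].res_id, end=rs[k - 1].res_id,
                    mean_z=float(z[start:k].mean())))
                start = None
    segments.sort(key=lambda s: (s.chain, s.start))
    return segments


# ---------------------------------------------------------------------------
# Kabsch superposition and loop grafting
# ---------------------------------------------------------------------------

def kabsch_superpose(coords_a, coords_b):
    """Least-squares rigid superposition of ``coords_a`` onto ``coords_b``.

    Returns ``(rotation, translation, rmsd)`` with a proper rotation
    (determinant +1) such that ``rotation @ a + translation ~ b``.
    Raises ``DegenerateGeometryError`` for fewer than 3 points or a
    (near-)collinear set.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise InputError(f"coordinate sets must match in shape, got {a.shape} "
                         f"and {b.shape}")
    if len(a) < 3:
        raise DegenerateGeometryError("need at least 3 points")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    for pts in (ac, bc):
        s = np.linalg.svd(pts, compute_uv=False)
        if s[1] <= 1e-8 * max(s[0], 1.0):
            raise DegenerateGeometryError("point set is (near-)collinear")
    h = ac.T @ bc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = b.mean(axis=0) - rot @ a.mean(axis=0)
    moved = a @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - b) ** 2, axis=1))))
    return rot, trans, rmsd


@dataclass(frozen=True)
class LoopGraftCandidate:
    target_chain: str
    target_start: int
    target_end: int
    donor_id: str
    donor_chain: str
    donor_start: int
    donor_end: int
    anchor_rmsd: float
    length_delta: int          # donor loop length - target loop length


def _segment_anchors(structure: StructureModel, segment, n_anchor: int):
    """(anchor coords, loop length) for a (chain, start, end) segment."""
    chain, start, end = segment
    ca = structure.ca_lookup(chain)
    ids = sorted(ca)
    if start not in ids or end not in ids or start > end:
        raise InputError(f"segment {chain}:{start}-{end} not in structure")
    i0, i1 = ids.index(start), ids.index(end)
    if i0 < n_anchor or i1 + n_anchor >= len(ids):
        raise InputError(
            f"segment {chain}:{start}-{end} lacks {n_anchor} flanking residues")
    anchor_ids = ids[i0 - n_anchor:i0] + ids[i1 + 1:i1 + 1 + n_anchor]
    coords = np.array([ca[r] for r in anchor_ids])
    loop_len = i1 - i0 + 1
    return coords, loop_len


def loop_graft_candidates(target: StructureModel, target_segment,
                          donors, n_anchor: int = 3,
                          anchor_rmsd_max: float = 1.0) -> list[LoopGraftCandidate]:
    """Screen donor loops for grafting into ``target_segment``.

    ``donors`` is a list of ``(donor_id, StructureModel, (chain, start, end))``.
    For each donor the 2 x ``n_anchor`` flanking Calphas are superposed onto
    the target's; candidates must have anchor RMSD <= ``anchor_rmsd_max`` and
    a strictly shorter loop.  Sorted by (length_delta, anchor RMSD).
    """
    t_anchor, t_len = _segment_anchors(target, target_segment, n_anchor)
    out = []
    for donor_id, donor, segment in donors:
        try:
            d_anchor, d_len = _segment_anchors(donor, segment, n_anchor)
        except InputError as exc:
            warnings.warn(f"donor {donor_id} skipped: {exc}", stacklevel=2)
            continue
        _, _, rmsd = kabsch_superpose(d_anchor, t_anchor)
        delta = d_len - t_len
        if rmsd <= anchor_rmsd_max and delta < 0:
            out.append(LoopGraftCandidate(
                target_chain=target_segment[0], target_start=target_segment[1],
                target_end=target_segment[2], donor_id=donor_id,
                donor_chain=segment[0], donor_start=segment[1],
                donor_end=segment[2], anchor_rmsd=rmsd, length_delta=delta))
    out.sort(key=lambda c: (c.length_delta, c.anchor_rmsd))
    return out
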