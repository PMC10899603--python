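"""Shared test utilities: independent oracles and tiny fixture builders.

The oracles here are deliberately naive (direct enumeration, fine-grid
scans) and never reuse the code paths they check.
"""

from __future__ import annotations

import numpy as np

from indikit.structure_screen import (
    CA_CB_SG_ANGLE,
    CB_SG_BOND,
    SS_BOND,
    DisulfideGeometry,
    StructureModel,
    place_atom,
)


# ---------------------------------------------------------------------------
# Consensus-calling oracle: direct per-column enumeration
# ---------------------------------------------------------------------------

def oracle_consensus_calls(records, reference_id, wt_max=0.30, cons_min=0.50,
                           min_cov=0.70):
    """Expected consensus calls from a list of (id, gapped seq) records."""
    ref = dict(records)[reference_id]
    homs = [s for rid, s in records if rid != reference_id]
    out = []
    pos = 0
    for col in range(len(ref)):
        if ref[col] == "-":
            continue
        pos += 1
        residues = [h[col] for h in homs if h[col] not in "-X"]
        cov = len(residues) / len(homs) if homs else 0.0
        if cov < min_cov or not residues:
            continue
        counts: dict[str, int] = {}
        for r in residues:
            counts[r] = counts.get(r, 0) + 1
        modal = min(counts, key=lambda r: (-counts[r], r))
        wt_f = counts.get(ref[col], 0) / len(residues)
        modal_f = counts[modal] / len(residues)
        if modal != ref[col] and wt_f <= wt_max and modal_f >= cons_min:
            out.append((pos, ref[col], modal))
    return out


def calls_as_tuples(calls):
    return [(c.ref_position, c.wt_residue, c.proposed_residue) for c in calls]


# ---------------------------------------------------------------------------
# Disulfide acceptance oracle: brute-force fine chi1 grid (no refinement)
# ---------------------------------------------------------------------------

def _sg_positions(frame, chi_values):
    n, ca, cb = frame
    return place_atom(n, ca, cb, CB_SG_BOND, CA_CB_SG_ANGLE, chi_values)


def oracle_disulfide_accept(frame_a, frame_b,
                            geom: DisulfideGeometry = DisulfideGeometry(),
                            step: float = 1.0) -> bool:
    """Accept decision from an exhaustive chi1 x chi1 scan at ``step`` degrees."""
    from indikit.structure_screen import dihedral_angle

    chi = np.arange(-180.0, 180.0, step)
    sa = _sg_positions(frame_a, chi)
    sb = _sg_positions(frame_b, chi)
    d = np.linalg.norm(sa[:, None, :] - sb[None, :, :], axis=-1)
    cba = np.broadcast_to(frame_a[2], sa.shape)
    cbb = np.broadcast_to(frame_b[2], sb.shape)
    chi3 = dihedral_angle(cba[:, None, :], sa[:, None, :], sb[None, :, :],
                          cbb[None, :, :])
    ok = (np.abs(d - SS_BOND) <= geom.ss_tol) \
        & (np.abs(chi3) >= geom.chi3_min) & (np.abs(chi3) <= geom.chi3_max)
    return bool(ok.any())


def rand_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def random_residue_frame(rng: np.random.Generator, cb: np.ndarray):
    """Random (N, CA, CB) frame with ideal bond geometry around ``cb``."""
    ca = cb + 1.53 * rand_unit(rng)
    refpt = cb + rand_unit(rng)
    n = place_atom(refpt, cb, ca, 1.458, 110.5, rng.uniform(-180, 180))
    return (n, ca, cb)


def random_pair_frames(rng: np.random.Generator):
    """Two random residue frames with Cbeta-Cbeta inside the prefilter window."""
    cb_a = np.zeros(3)
    cb_b = rng.uniform(3.0, 5.0) * rand_unit(rng)
    return random_residue_frame(rng, cb_a), random_residue_frame(rng, cb_b)


# ---------------------------------------------------------------------------
# Minimal structure builders
# ---------------------------------------------------------------------------

def ca_only_structure(res_ids, coords, chain="A", b_factors=None,
                      chains=None) -> StructureModel:
    """A StructureModel with one Calpha atom per residue."""
    coords = np.asarray(coords, dtype=float)
    n = len(res_ids)
    b = np.full(n, 20.0) if b_factors is None else np.asarray(b_factors, float)
    ch = np.full(n, chain) if chains is None else np.asarray(chains)
    return StructureModel(
        chain=ch, res_id=np.asarray(res_ids, dtype=int),
        icode=np.array([""] * n), res_name=np.array(["ALA"] * n),
        atom_name=np.array(["CA"] * n), coord=coords,
        b_factor=b, occupancy=np.ones(n), hetero=np.zeros(n, dtype=bool))
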