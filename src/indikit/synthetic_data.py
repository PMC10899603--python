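"""Seeded generators emulating the statistical structure of the data each
pipeline stage expects.

Every downstream stage can be exercised without downloads: homolog MSAs with
planted consensus signals, poly-alanine coordinate models with plantable
disulfide geometry and B-factor hotspots, Boltzmann-sigmoid melt curves,
first-order photolysis decays, synthetic price distributions, and denim-like
reflectance spectra.  Generators are deterministic (one integer seed, no
global random state); when asked to write files they also serialize the
ground truth as a JSON sidecar, and identical specs produce byte-identical
output.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import _cie_data
from .errors import InfeasibleSpecError, InputError
from .msa_consensus import AMINO_ACIDS, Alignment, write_alignment
from .structure_screen import (
    CA_CB_SG_ANGLE,
    CB_SG_BOND,
    CHI3_IDEAL,
    SS_BOND,
    StructureModel,
    place_atom,
    reconstruct_cb,
)

#: The ten stabilizing substitutions of the engineered decatuple variant,
#: used as the default planted consensus signal.
STABLE_VARIANT_SITES: tuple[tuple[int, str, str], ...] = (
    (75, "E", "P"), (86, "Q", "K"), (110, "S", "V"), (188, "I", "L"),
    (222, "G", "D"), (296, "G", "L"), (297, "V", "G"), (388, "T", "A"),
    (413, "S", "K"), (430, "G", "K"),
)


def _write_sidecar(path: Path, truth: dict) -> None:
    def convert(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    path.write_text(json.dumps(truth, indent=2, sort_keys=True,
                               default=convert) + "\n")


# ---------------------------------------------------------------------------
# MSA with planted consensus signals
# ---------------------------------------------------------------------------

def gen_msa(seed: int, n_homologs: int = 18, ref_length: int = 460,
            identity_range: tuple[float, float] = (0.62, 0.95),
            planted_calls=STABLE_VARIANT_SITES,
            majority_fraction: float = 0.6,
            reference_id: str = "REF",
            out_dir=None) -> tuple[Alignment, dict]:
    """Homolog set with consensus substitutions planted at chosen positions.

    Homologs are mutated copies of a random reference hitting target pairwise
    identities drawn from ``identity_range``.  At each planted position a
    fixed ``majority_fraction`` of homologs carries the consensus residue,
    ~15% keep wildtype and the rest get scattered other residues, so the
    default calling thresholds are satisfied with margin.  Returns the
    alignment and a ground-truth record; with ``out_dir`` the FASTA plus a
    JSON sidecar are written.
    """
    rng = np.random.default_rng(seed)
    planted = [(int(p), wt, cons) for p, wt, cons in planted_calls]
    positions = [p for p, _, _ in planted]
    if len(set(positions)) != len(positions):
        raise InfeasibleSpecError("planted positions must be distinct")
    if any(not 1 <= p <= ref_length for p in positions):
        raise InfeasibleSpecError("planted position outside reference length")

    aa = np.array(list(AMINO_ACIDS))
    ref = rng.choice(aa, size=ref_length)
    for pos, wt, _ in planted:
        ref[pos - 1] = wt

    n_cons = int(round(majority_fraction * n_homologs))
    n_wt = int(np.floor(0.15 * n_homologs))
    if n_cons + n_wt > n_homologs or n_cons < 1:
        raise InfeasibleSpecError("majority fraction incompatible with "
                                  "homolog count")
    min_identity = identity_range[0]
    max_mismatch = int(round((1 - min_identity) * ref_length))
    if len(planted) > max_mismatch:
        raise InfeasibleSpecError("planted density incompatible with the "
                                  "identity range")

    homologs = np.tile(ref, (n_homologs, 1))
    # planted columns: assign consensus / wildtype / other per homolog
    for pos, wt, cons in planted:
        order = rng.permutation(n_homologs)
        col = np.empty(n_homologs, dtype=homologs.dtype)
        col[order[:n_cons]] = cons
        col[order[n_cons:n_cons + n_wt]] = wt
        others = [r for r in AMINO_ACIDS if r not in (wt, cons)]
        col[order[n_cons + n_wt:]] = rng.choice(others,
                                                size=n_homologs - n_cons - n_wt)
        homologs[:, pos - 1] = col

    identities = rng.uniform(*identity_range, size=n_homologs)
    planted_idx = np.array([p - 1 for p in positions], dtype=int)
    background = np.setdiff1d(np.arange(ref_length), planted_idx)
    for h in range(n_homologs):
        target_mm = int(round((1 - identities[h]) * ref_length))
        already = int(np.sum(homologs[h] != ref))
        extra = target_mm - already
        if extra < 0:
            raise InfeasibleSpecError(
                f"homolog {h}: planted mismatches exceed identity budget")
        sites = rng.choice(background, size=extra, replace=False)
        for s in sites:
            choices = [r for r in AMINO_ACIDS if r != ref[s]]
            homologs[h, s] = choices[rng.integers(len(choices))]

    records = [(reference_id, "".join(ref))]
    records += [(f"HOM{h + 1:02d}", "".join(homologs[h]))
                for h in range(n_homologs)]
    aln = Alignment(tuple(records), reference_id)
    truth = {
        "seed": seed,
        "planted_calls": [{"ref_position": p, "wt": wt, "proposed": cons}
                          for p, wt, cons in planted],
        "target_identities": {f"HOM{h + 1:02d}": float(identities[h])
                              for h in range(n_homologs)},
        "majority_fraction": majority_fraction,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_alignment(aln, out_dir / "msa.fasta")
        _write_sidecar(out_dir / "msa.truth.json", truth)
    return aln, truth


# ---------------------------------------------------------------------------
# Coordinates with plantable disulfide geometry and B-factor hotspots
# ---------------------------------------------------------------------------

def ideal_disulfide_residues(chi1_a: float = -65.0, chi1_b: float = -65.0,
                             chi3: float = CHI3_IDEAL,
                             ss_bond: float = SS_BOND) -> tuple[dict, dict]:
    """Two cysteine-like residues built at textbook disulfide geometry.

    Internal coordinates use the same constants as the disulfide scanner, so
    a scan with the given chi1 values on its grid recovers the planted
    Sgamma positions exactly (strain ~ 0 at default arguments).
    """
    ca_a = np.zeros(3)
    cb_a = np.array([1.53, 0.0, 0.0])
    ang = np.radians(110.5)
    n_a = ca_a + 1.458 * np.array([np.cos(ang), np.sin(ang), 0.0])
    sg_a = place_atom(n_a, ca_a, cb_a, CB_SG_BOND, CA_CB_SG_ANGLE, chi1_a)
    sg_b = place_atom(ca_a, cb_a, sg_a, ss_bond, 104.15, -85.0)
    cb_b = place_atom(cb_a, sg_a, sg_b, CB_SG_BOND, 104.15, chi3)
    ca_b = place_atom(sg_a, sg_b, cb_b, 1.53, CA_CB_SG_ANGLE, -75.0)
    n_b = place_atom(sg_b, cb_b, ca_b, 1.458, 110.5, chi1_b)
    c_a = place_atom(cb_a, n_a, ca_a, 1.52, 111.0, -122.0)
    c_b = place_atom(cb_b, n_b, ca_b, 1.52, 111.0, -122.0)
    res_a = {"N": n_a, "CA": ca_a, "C": c_a, "CB": cb_a, "SG": sg_a}
    res_b = {"N": n_b, "CA": ca_b, "C": c_b, "CB": cb_b, "SG": sg_b}
    return res_a, res_b


def _assemble_structure(residues: list[tuple[str, int, str, dict, float]],
                        model_id: int = 1) -> StructureModel:
    """Build a StructureModel from (chain, res_id, res_name, atoms, b)."""
    chain, res_id, icode, res_name, atom_name = [], [], [], [], []
    coord, b_factor = [], []
    order = ("N", "CA", "C", "O", "CB", "SG")
    for ch, rid, rname, atoms, b in residues:
        for name in order:
            if name in atoms:
                chain.append(ch)
                res_id.append(rid)
                icode.append("")
                res_name.append(rname)
                atom_name.append(name)
                coord.append(np.asarray(atoms[name], dtype=float))
                b_factor.append(b)
    n = len(atom_name)
    return StructureModel(
        chain=np.array(chain), res_id=np.array(res_id, dtype=int),
        icode=np.array(icode), res_name=np.array(res_name),
        atom_name=np.array(atom_name), coord=np.array(coord),
        b_factor=np.array(b_factor, dtype=float),
        occupancy=np.ones(n), hetero=np.zeros(n, dtype=bool),
        model_id=model_id)


def gen_structure(seed: int, n_residues: int = 400,
                  planted_ss_pairs: list[tuple[int, int]] = (),
                  b_hotspots: list[tuple[int, int]] = (),
                  chain: str = "A", min_sep: int = 3,
                  out_dir=None) -> tuple[StructureModel, dict]:
    """Poly-alanine model on an idealized helical path.

    Residues named in ``planted_ss_pairs`` are repositioned (as cysteines,
    isolated from the helix) at ideal disulfide geometry; B-factors are a
    baseline of 20 with a short-period ripple plus Gaussian bumps (peak +30)
    over each hotspot range, so only hotspots survive z-scoring.
    """
    rng = np.random.default_rng(seed)
    for i, j in planted_ss_pairs:
        if not (1 <= i <= n_residues and 1 <= j <= n_residues):
            raise InfeasibleSpecError("planted pair outside residue range")
        if abs(i - j) < min_sep:
            raise InfeasibleSpecError(
                f"planted pair {(i, j)} closer than min_sep={min_sep}")
    for lo, hi in b_hotspots:
        if not 1 <= lo <= hi <= n_residues:
            raise InfeasibleSpecError(f"hotspot {(lo, hi)} out of range")

    # idealized alpha-helix Calpha path
    k = np.arange(n_residues)
    theta = np.radians(100.0) * k
    ca = np.stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * k], axis=1)

    idx = np.arange(1, n_residues + 1)
    b = 20.0 + 2.0 * np.sin(2 * np.pi * k / 7.0) \
        + rng.normal(0.0, 0.05, n_residues)
    for lo, hi in b_hotspots:
        center = (lo + hi) / 2.0
        width = max((hi - lo) / 4.0, 1.0)
        b += 30.0 * np.exp(-0.5 * ((idx - center) / width) ** 2)

    planted_map: dict[int, dict] = {}
    for p, (i, j) in enumerate(planted_ss_pairs):
        res_a, res_b = ideal_disulfide_residues()
        offset = np.array([60.0 + 30.0 * p, -40.0, 10.0 * p])
        planted_map[i] = {k_: v + offset for k_, v in res_a.items()}
        planted_map[j] = {k_: v + offset for k_, v in res_b.items()}

    residues = []
    for r in range(n_residues):
        rid = r + 1
        if rid in planted_map:
            residues.append((chain, rid, "CYS", planted_map[rid], float(b[r])))
            continue
        prev_ca = ca[r - 1] if r > 0 else 2 * ca[0] - ca[1]
        next_ca = ca[r + 1] if r < n_residues - 1 else 2 * ca[-1] - ca[-2]
        to_prev = (prev_ca - ca[r]) / np.linalg.norm(prev_ca - ca[r])
        to_next = (next_ca - ca[r]) / np.linalg.norm(next_ca - ca[r])
        n_at = ca[r] + 1.458 * to_prev
        c_at = ca[r] + 1.525 * to_next
        cb = reconstruct_cb(n_at, ca[r], c_at)
        residues.append((chain, rid, "ALA",
                         {"N": n_at, "CA": ca[r], "C": c_at, "CB": cb},
                         float(b[r])))
    model = _assemble_structure(residues)
    truth = {
        "seed": seed,
        "n_residues": n_residues,
        "planted_ss_pairs": [list(p) for p in planted_ss_pairs],
        "b_hotspots": [list(h) for h in b_hotspots],
        "chain": chain,
    }
    if out_dir is not None:
        from .structure_screen import write_structure

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_structure(model, out_dir / "model.pdb")
        _write_sidecar(out_dir / "model.truth.json", truth)
    return model, truth


# ---------------------------------------------------------------------------
# Melt curves
# ---------------------------------------------------------------------------

def gen_melt_curves(seed: int,
                    variants: list[tuple[str, float, float]] = (
                        ("WT", 55.0, 1.4), ("stable", 68.1, 1.4)),
                    replicates: int = 3, noise_sd: float = 0.02,
                    t_min: float = 25.0, t_max: float = 99.0,
                    t_step: float = 0.5,
                    out_dir=None) -> tuple[pd.DataFrame, dict]:
    """Boltzmann-sigmoid DSF traces with Gaussian noise.

    ``noise_sd`` is a fraction of the transition amplitude.  Default variants
    are a wildtype and a stabilized variant 13.1 C apart, mirroring the
    engineering campaign's headline shift.  Columns: variant, replicate,
    temperature_C, fluorescence.
    """
    rng = np.random.default_rng(seed)
    temps = np.arange(t_min, t_max + t_step / 2, t_step)
    rows = []
    truth_variants = []
    for name, tm, slope in variants:
        if not t_min < tm < t_max:
            raise InputError(f"true Tm {tm} outside the temperature grid")
        truth_variants.append({"variant": name, "tm": float(tm),
                               "slope": float(slope)})
        for rep in range(1, replicates + 1):
            f = 0.1 + 1.0 / (1.0 + np.exp((tm - temps) / slope))
            f = f + rng.normal(0.0, noise_sd * 1.0, len(temps))
            for t, y in zip(temps, f):
                rows.append((name, rep, float(t), float(y)))
    df = pd.DataFrame(rows, columns=["variant", "replicate", "temperature_C",
                                     "fluorescence"])
    truth = {"seed": seed, "variants": truth_variants,
             "replicates": replicates, "noise_sd": noise_sd}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_dir / "melt_curves.csv", index=False)
        _write_sidecar(out_dir / "melt_curves.truth.json", truth)
    return df, truth


# ---------------------------------------------------------------------------
# First-order decays
# ---------------------------------------------------------------------------

def gen_decay(seed: int, k: float = 0.5, a0: float = 100.0,
              timepoints=None, noise_sd: float = 0.05,
              kind: str = "peak_area",
              out_dir=None) -> tuple[pd.DataFrame, dict]:
    """Exponential decay samples with multiplicative Gaussian noise.

    ``noise_sd`` is the relative noise per point.  Default time points span
    six hours, as for a photolysis progress curve.  Columns: time_h, signal,
    kind.
    """
    if k < 0 or a0 <= 0:
        raise InputError("need k >= 0 and a0 > 0")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 6.0, 13) if timepoints is None \
        else np.asarray(timepoints, dtype=float)
    signal = a0 * np.exp(-k * t) * (1.0 + rng.normal(0.0, noise_sd, len(t)))
    signal = np.maximum(signal, 0.0)
    df = pd.DataFrame({"time_h": t, "signal": signal, "kind": kind})
    truth = {"seed": seed, "k": float(k), "a0": float(a0),
             "noise_sd": noise_sd, "kind": kind}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_dir / "decay.csv", index=False)
        _write_sidecar(out_dir / "decay.truth.json", truth)
    return df, truth


# ---------------------------------------------------------------------------
# Price distributions
# ---------------------------------------------------------------------------

def gen_price_distributions(seed: int, items: dict | None = None,
                            span: float = 0.5, n_samples: int = 1000,
                            out_dir=None):
    """Synthetic price distributions (default: triangular, mode at the printed
    price, +/- ``span``) for the key raw materials, plus a sampled table."""
    from .tea import PriceDistribution, default_price_table, \
        triangular_from_point

    prices = default_price_table()
    if items is None:
        items = {name: None for name in ("enzymes", "sucrose", "indoxyl")}
    dists: dict[str, PriceDistribution] = {}
    for name, spec in items.items():
        if spec is None:
            dists[name] = triangular_from_point(name, prices[name].value, span)
        else:
            family = spec["family"]
            params = {k: float(v) for k, v in spec.items() if k != "family"}
            dists[name] = PriceDistribution(name, family, params)
    rng = np.random.default_rng(seed)
    table = pd.DataFrame({name: d.sample(rng, n_samples)
                          for name, d in dists.items()})
    truth = {"seed": seed, "span": span,
             "families": {k: d.family for k, d in dists.items()},
             "analytic_means": {k: d.mean() for k, d in dists.items()}}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "price_samples.csv", index=False)
        _write_sidecar(out_dir / "price_samples.truth.json", truth)
    return dists, table, truth


# ---------------------------------------------------------------------------
# Reflectance spectra
# ---------------------------------------------------------------------------

_TEMPLATES = ("denim_blue", "undyed", "gray")


def _template_curve(template: str, wl: np.ndarray, depth: float) -> np.ndarray:
    if template == "denim_blue":
        base = 0.04 + 0.08 * (1.0 - depth)
        peak = 0.45 * (1.0 - 0.7 * depth)
        return base + peak * np.exp(-0.5 * ((wl - 450.0) / 55.0) ** 2)
    if template == "undyed":
        return 0.60 + 0.15 * (wl - 400.0) / 300.0
    if template == "gray":
        return np.full_like(wl, 0.18)
    raise InputError(f"unknown template {template!r}; choose from {_TEMPLATES}")


def gen_reflectance(seed: int, template: str = "denim_blue",
                    depth: float = 0.5, noise: float = 0.002,
                    n_measurements: int = 5, sample: str | None = None,
                    out_dir=None) -> tuple[pd.DataFrame, dict]:
    """Smooth reflectance spectra for denim-like, undyed, or gray fabric.

    ``depth`` in [0, 1] deepens the blue dye (lower, narrower reflectance);
    the denim template keeps b* < 0 at any depth.  Noise is additive Gaussian
    per wavelength.  Long-format columns: sample, wavelength_nm, reflectance.
    """
    if not 0.0 <= depth <= 1.0:
        raise InputError("depth must be in [0, 1]")
    rng = np.random.default_rng(seed)
    wl = _cie_data.default_grid()
    base = _template_curve(template, wl, depth)
    sample = sample or template
    rows = []
    for m in range(1, n_measurements + 1):
        r = np.maximum(base + rng.normal(0.0, noise, len(wl)), 0.0)
        name = f"{sample}_{m}" if n_measurements > 1 else sample
        for w, v in zip(wl, r):
            rows.append((name, float(w), float(v)))
    df = pd.DataFrame(rows, columns=["sample", "wavelength_nm", "reflectance"])
    truth = {"seed": seed, "template": template, "depth": depth,
             "noise": noise, "n_measurements": n_measurements}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_dir / "spectra.csv", index=False)
        _write_sidecar(out_dir / "spectra.truth.json", truth)
    return df, truth
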