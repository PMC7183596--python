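"""Synthetic fixtures: toy structures, corrupted predictions, decoy pools.

Everything the pipeline consumes can be generated here with known ground
truth: ideal-geometry backbones built from dihedral angles, prediction files
derived from a structure and corrupted at a controlled rate (so every binary
penalty is analytically ε in expectation), and feature-space decoy pools
with a planted linear relation between features and GDT-TS. The pool
generator mirrors the shape of a CASP fitting set — by default 75 targets
with 400 decoys each, qualities mostly below 50 GDT-TS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import pdist, squareform

from .features import (
    FeatureVector,
    PredictionSet,
    assign_secondary_structure,
    compute_sasa,
    sa_binarize,
)
from .scoring import PUBLISHED_WEIGHTS, PoolModel, TargetPool, WeightVector
from .structure_io import ContactPrediction, ProteinModel, Residue, SAPrediction, SSPrediction

__all__ = [
    "FixtureSpec",
    "make_helix",
    "make_strand",
    "make_coil",
    "make_antiparallel_sheet",
    "derive_predictions",
    "make_decoy_pools",
    "write_fixture_tree",
    "write_pdb",
]

# Ideal backbone internal coordinates (Å, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.521
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8

HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-139.0, 135.0)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position atom D from A, B, C given |CD|, ∠BCD and torsion A-B-C-D."""
    ang, tor = math.radians(angle_deg), math.radians(torsion_deg)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d = np.array([-bond * math.cos(ang),
                  bond * math.sin(ang) * math.cos(tor),
                  bond * math.sin(ang) * math.sin(tor)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _cb_position(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Tetrahedral Cβ from the backbone N, Cα, C positions."""
    u = _unit(n - ca)
    v = _unit(c - ca)
    bis = _unit(u + v)
    perp = _unit(np.cross(v, u))
    cos_t = math.cos(math.radians(110.1))
    a = cos_t / (bis @ u)
    b = math.sqrt(max(0.0, 1.0 - a * a))
    return ca + _B_CA_CB * (a * bis + b * perp)


def build_backbone(phi_psi: list[tuple[float, float]],
                   residue_names: Optional[list[str]] = None,
                   start_number: int = 1,
                   model_id: str = "backbone") -> ProteinModel:
    """Build a poly-peptide backbone (N, Cα, C, O, Cβ) from dihedral angles."""
    n = len(phi_psi)
    if n < 2:
        raise ValueError("need at least 2 residues")
    if residue_names is None:
        residue_names = ["ALA"] * n
    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (_B_N_CA, 0.0, 0.0)
    ang = math.radians(_A_N_CA_C)
    C[0] = CA[0] + _B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    for i in range(1, n):
        psi_prev = phi_psi[i - 1][1]
        phi = phi_psi[i][0]
        N[i] = _place(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, psi_prev)
        CA[i] = _place(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA, 180.0)
        C[i] = _place(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, phi)
    residues = []
    for i in range(n):
        psi = phi_psi[i][1]
        O = _place(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, psi + 180.0)
        atoms = {"N": N[i], "CA": CA[i], "C": C[i], "O": O}
        if residue_names[i] != "GLY":
            atoms["CB"] = _cb_position(N[i], CA[i], C[i])
        residues.append(Residue(number=start_number + i,
                                name=residue_names[i], atoms=atoms))
    return ProteinModel(model_id=model_id, residues=residues)


def make_helix(n: int) -> ProteinModel:
    """Ideal poly-ALA α-helix (φ = −57°, ψ = −47°)."""
    return build_backbone([HELIX_PHI_PSI] * n, model_id=f"helix{n}")


def make_strand(n: int) -> ProteinModel:
    """Single ideal extended β-strand (φ = −139°, ψ = 135°)."""
    return build_backbone([STRAND_PHI_PSI] * n, model_id=f"strand{n}")


def make_coil(n: int, seed: int = 0) -> ProteinModel:
    """Random-coil backbone with uniformly sampled dihedrals; deterministic."""
    rng = np.random.default_rng(seed)
    angles = [(float(rng.uniform(-180, 180)), float(rng.uniform(-180, 180)))
              for _ in range(n)]
    return build_backbone(angles, model_id=f"coil{n}s{seed}")


@lru_cache(maxsize=4)
def make_antiparallel_sheet(n_per_strand: int = 6) -> ProteinModel:
    """Two-strand antiparallel β fixture with inter-strand hydrogen bonds.

    The second strand is rigid-body placed against the first by minimizing
    the deviation of amide-H···carbonyl-O distances from 1.9 Å at the
    hydrogen-bonded residue pairs of the ladder, plus paired Cα separations
    near 5 Å and a soft clash penalty. The amide H is reconstructed 1.0 Å
    from N along the preceding carbonyl C→O direction reversed.
    """
    from scipy.spatial.transform import Rotation

    m = n_per_strand
    s1 = build_backbone([STRAND_PHI_PSI] * m, model_id="sheetA")
    s2 = build_backbone([STRAND_PHI_PSI] * m, model_id="sheetB")

    def coords(model: ProteinModel) -> dict[str, np.ndarray]:
        return {name: np.array([r.atoms[name] for r in model.residues])
                for name in ("N", "CA", "C", "O", "CB")}

    def amide_h(c: dict[str, np.ndarray]) -> np.ndarray:
        """H on N(i), i >= 1, pointing back along the previous C=O."""
        h = np.full_like(c["N"], np.nan)
        for i in range(1, len(c["N"])):
            d = c["C"][i - 1] - c["O"][i - 1]
            h[i] = c["N"][i] + d / np.linalg.norm(d)
        return h

    c1, c2 = coords(s1), coords(s2)
    h1 = amide_h(c1)

    def transform(params: np.ndarray, pts: np.ndarray) -> np.ndarray:
        rot = Rotation.from_rotvec(params[:3])
        return pts @ rot.as_matrix().T + params[3:]

    pair_j = [m - 1 - i for i in range(m)]  # antiparallel register

    def loss(params: np.ndarray) -> float:
        t2 = {k: transform(params, v) for k, v in c2.items()}
        h2 = amide_h(t2)
        total = 0.0
        for i in range(m):
            j = pair_j[i]
            total += (np.linalg.norm(c1["CA"][i] - t2["CA"][j]) - 5.0) ** 2
            if i % 2 == 0:  # hydrogen-bonded pairs of the antiparallel ladder
                if np.all(np.isfinite(h2[j])):
                    total += (np.linalg.norm(c1["O"][i] - h2[j]) - 1.9) ** 2
                if np.all(np.isfinite(h1[i])):
                    total += (np.linalg.norm(h1[i] - t2["O"][j]) - 1.9) ** 2
        # soft clash penalty between all heavy atoms of the two strands
        A = np.vstack(list(c1.values()))
        B = np.vstack(list(t2.values()))
        d = np.linalg.norm(A[:, None, :] - B[None, :, :], axis=-1)
        total += np.sum(np.maximum(0.0, 2.6 - d) ** 2) * 10.0
        return float(total)

    # start: flip the second strand and offset it sideways
    best = None
    for dy in (4.5, 5.0, -4.5, -5.0):
        for rx in (math.pi, 0.9 * math.pi, 1.1 * math.pi):
            x0 = np.array([rx, 0.0, 0.0, 0.0, dy, 0.0])
            res = minimize(loss, x0, method="Powell",
                           options={"maxiter": 20000, "xtol": 1e-6})
            if best is None or res.fun < best.fun:
                best = res
        if best.fun < 1.0:  # ladder geometry already satisfied
            break
    residues = list(s1.residues)
    for k, r in enumerate(s2.residues):
        atoms = {name: transform(best.x, xyz[None, :])[0]
                 for name, xyz in r.atoms.items()}
        residues.append(Residue(number=m + 3 + k, name=r.name, atoms=atoms))
    return ProteinModel(model_id=f"sheet{m}x2", residues=residues)


# ---------------------------------------------------------------------------
# Predictions with controlled corruption

#: per-residue DOPE / GOAP pseudo-potentials as a function of corruption rate;
#: lower (more negative) = better, linear in ε
_DOPE_PER_RES = (-110.0, 60.0)
_GOAP_PER_RES = (-12.0, 6.0)


def derive_predictions(model: ProteinModel, corruption_rate: float,
                       seed: int = 0, sasa_points: int = 960) -> PredictionSet:
    """Predictions derived from the model itself, corrupted at rate ε.

    Each secondary-structure position flips to a random other class with
    probability ε; each accessibility bit flips with probability ε; each true
    (≤ 8 Å) contact pair is independently replaced with probability ε by a
    random distant (> 8 Å) pair, so the contact penalty is Binomial(L, ε)/L.
    Pseudo DOPE/GOAP totals are emitted as a stated linear function of ε.
    """
    eps = float(corruption_rate)
    if not 0.0 <= eps <= 1.0:
        raise ValueError("corruption_rate must lie in [0,1]")
    rng = np.random.default_rng(seed)
    numbers = model.residue_numbers
    n_pos = max(numbers)

    # secondary structure, laid out by residue number
    ss_true = assign_secondary_structure(model)
    ss_full = ["C"] * n_pos
    for res, cls in zip(model.residues, ss_true):
        ss_full[res.number - 1] = cls
    for k in range(n_pos):
        if rng.random() < eps:
            others = [c for c in "HEC" if c != ss_full[k]]
            ss_full[k] = others[rng.integers(len(others))]

    # solvent accessibility
    sa_true = sa_binarize(compute_sasa(model, n_points=sasa_points), model)
    sa_full = ["b"] * n_pos
    for res, bit in zip(model.residues, sa_true):
        sa_full[res.number - 1] = "e" if bit == "1" else "b"
    for k in range(n_pos):
        if rng.random() < eps:
            sa_full[k] = "b" if sa_full[k] == "e" else "e"

    # contacts
    ref = model.reference_coordinates()
    ok = np.all(np.isfinite(ref), axis=1)
    dmat = squareform(pdist(np.nan_to_num(ref)))
    true_pairs: list[tuple[int, int]] = []
    far_pairs: list[tuple[int, int]] = []
    for a in range(len(numbers)):
        for b in range(a + 1, len(numbers)):
            if not (ok[a] and ok[b]):
                continue
            pair = (min(numbers[a], numbers[b]), max(numbers[a], numbers[b]))
            (true_pairs if dmat[a, b] <= 8.0 else far_pairs).append(pair)
    listed: dict[tuple[int, int], float] = {}
    far_order = rng.permutation(len(far_pairs))
    far_cursor = 0
    for pair in true_pairs:
        conf = 1.0 - eps * rng.random()
        if eps > 0 and rng.random() < eps and far_cursor < len(far_pairs):
            pair = far_pairs[far_order[far_cursor]]
            far_cursor += 1
        if pair not in listed:
            listed[pair] = conf
    contacts = (ContactPrediction([(i, j, c) for (i, j), c in listed.items()])
                if listed else None)

    n = len(model)
    dope = {model.model_id: n * (_DOPE_PER_RES[0] + _DOPE_PER_RES[1] * eps)}
    goap = {model.model_id: n * (_GOAP_PER_RES[0] + _GOAP_PER_RES[1] * eps)}
    return PredictionSet(ss=SSPrediction("".join(ss_full)),
                         sa=SAPrediction("".join(sa_full)),
                         contacts=contacts, dope=dope, goap=goap)


# ---------------------------------------------------------------------------
# Planted-weight decoy pools

@dataclass
class FixtureSpec:
    """Conditions for the planted-weight benchmark and fixture trees.

    Defaults mirror the shape of the CASP12 fitting set (75 targets, 400
    decoys each) with the published weights as the planted truth and a
    quality noise of 2 GDT-TS units.
    """

    n_targets: int = 75
    decoys_per_target: int = 400
    true_weights: WeightVector = field(default_factory=lambda: PUBLISHED_WEIGHTS)
    noise_sd: float = 2.0
    corruption_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.decoys_per_target < 2:
            raise ValueError("need at least 2 decoys per target")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.corruption_rate <= 1.0:
            raise ValueError("corruption_rate must lie in [0,1]")


def make_decoy_pools(spec: FixtureSpec) -> list[TargetPool]:
    """Feature-space decoy pools with a planted linear quality relation.

    Penalty features are uniform on [0,1]; normalized potentials are Gaussian
    around a target-specific location. GDT-TS is an exact global linear
    function of the features (plus Gaussian noise), centred near 37 and
    scaled to span roughly [10, 65] so most decoys sit in the poor-quality
    regime; TM-scores are a fixed monotone map of GDT-TS.
    """
    rng = np.random.default_rng(spec.seed)
    w = spec.true_weights.as_array()
    all_features: list[np.ndarray] = []
    for _t in range(spec.n_targets):
        m = spec.decoys_per_target
        F = np.empty((m, 6))
        mu_dope = rng.uniform(-115.0, -95.0)
        mu_goap = rng.uniform(-14.0, -10.0)
        F[:, 0] = rng.normal(mu_dope, 2.0, size=m)
        F[:, 1] = rng.normal(mu_goap, 2.0, size=m)
        F[:, 2:] = rng.random((m, 4))
        all_features.append(F)

    scores = np.concatenate([F @ w for F in all_features])
    scale = 9.0 / scores.std()
    offset = 37.0 + scale * scores.mean()

    pools: list[TargetPool] = []
    for t, F in enumerate(all_features):
        quality = offset - scale * (F @ w)
        quality = quality + rng.normal(0.0, spec.noise_sd, size=len(F))
        quality = np.clip(quality, 0.0, 100.0)
        models = [
            PoolModel(model_id=f"T{t:03d}_m{k:04d}",
                      features=FeatureVector.from_array(F[k]),
                      gdt_ts=float(quality[k]),
                      tm_score=float(np.clip(0.1 + 0.008 * quality[k], 0.0, 1.0)))
            for k in range(len(F))
        ]
        pools.append(TargetPool(target_id=f"T{t:03d}", models=models))
    return pools


# ---------------------------------------------------------------------------
# On-disk fixture trees

def write_pdb(model: ProteinModel, path: str | Path) -> None:
    """Write a minimal single-chain ATOM-record PDB file."""
    lines = []
    serial = 1
    for res in model.residues:
        for name, xyz in res.atoms.items():
            elem = name.strip().lstrip("0123456789")[:1]
            name_field = name if len(name) >= 4 else f" {name:<3}"
            lines.append(
                f"ATOM  {serial:5d} {name_field}{'':1}{res.name:>3} A"
                f"{res.number:4d}{res.icode:1s}   "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {elem:>2}"
            )
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_fixture_tree(out_dir: str | Path, spec: FixtureSpec,
                       n_res: int = 48, sasa_points: int = 240) -> list[str]:
    """Write a directory of per-target decoy pools in the pipeline's dialects.

    Layout: ``{target}/{model}.pdb`` for the decoys plus ``{target}.rr``,
    ``{target}.ss``, ``{target}.acc`` and ``{target}.scores`` (model id,
    GDT-TS, TM-score, raw DOPE, raw GOAP). Each target's first decoy is the
    reference structure the predictions were derived from; the others are
    coordinate-perturbed copies with correspondingly worse labels.
    Returns the target ids written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    target_ids = []
    for t in range(spec.n_targets):
        target_id = f"T{t:03d}"
        target_ids.append(target_id)
        tdir = out_dir / target_id
        tdir.mkdir(exist_ok=True)
        reference = make_coil(n_res, seed=int(rng.integers(2 ** 31 - 1)))
        preds = derive_predictions(reference, spec.corruption_rate,
                                   seed=int(rng.integers(2 ** 31 - 1)),
                                   sasa_points=sasa_points)
        ss_path = out_dir / f"{target_id}.ss"
        ss_path.write_text(preds.ss.classes + "\n")
        (out_dir / f"{target_id}.acc").write_text(preds.sa.classes + "\n")
        rr_lines = [f"{i} {j} 0 8 {conf:.4f}"
                    for i, j, conf in preds.contacts.pairs]
        (out_dir / f"{target_id}.rr").write_text("\n".join(rr_lines) + "\n")

        score_rows = ["model gdt_ts tm_score dope goap"]
        sigmas = np.concatenate([[0.0], np.linspace(
            0.4, 3.0, spec.decoys_per_target - 1)])
        for k, sigma in enumerate(sigmas):
            model_id = f"{target_id}_m{k:03d}"
            residues = []
            for r in reference.residues:
                atoms = {name: xyz + rng.normal(0.0, sigma, 3)
                         for name, xyz in r.atoms.items()}
                residues.append(Residue(number=r.number, name=r.name,
                                        atoms=atoms))
            decoy = ProteinModel(model_id=model_id, residues=residues)
            write_pdb(decoy, tdir / f"{model_id}.pdb")
            gdt = float(np.clip(
                62.0 * math.exp(-sigma / 1.8) + rng.normal(0, 1.0), 1.0, 100.0))
            tm = float(np.clip(0.1 + 0.008 * gdt, 0.0, 1.0))
            dope = n_res * (_DOPE_PER_RES[0] + 9.0 * sigma + rng.normal(0, 0.5))
            goap = n_res * (_GOAP_PER_RES[0] + 1.1 * sigma + rng.normal(0, 0.1))
            score_rows.append(
                f"{model_id} {gdt:.2f} {tm:.3f} {dope:.1f} {goap:.1f}")
        (out_dir / f"{target_id}.scores").write_text("\n".join(score_rows) + "\n")
    return target_ids
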