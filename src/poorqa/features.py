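"""The six features of the linear quality score.

A model's score combines two normalized statistical potentials (DOPE, GOAP,
consumed as precomputed totals) with four structural penalty terms in [0,1]:
helix and strand secondary-structure disagreement, solvent-accessibility
disagreement, and predicted-contact violation. Secondary structure and
solvent-accessible surface area of the model are computed internally
(Kabsch–Sander hydrogen-bond assignment; Shrake–Rupley sphere sampling), with
the option to supply a parsed DSSP output file instead.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import (
    ContactPrediction,
    ProteinModel,
    SAPrediction,
    SSPrediction,
)

__all__ = [
    "FEATURE_NAMES",
    "MAX_ASA",
    "FeatureFailure",
    "FeatureVector",
    "PredictionSet",
    "binary_xor_penalty",
    "assign_secondary_structure",
    "compute_sasa",
    "sa_binarize",
    "ss_penalties",
    "sa_penalty",
    "contact_penalty",
    "normalize_potential",
    "build_feature_vector",
]

#: Canonical feature order used everywhere weights meet features.
FEATURE_NAMES = ("dope", "goap", "ss_h", "ss_e", "sa", "contact")

#: Theoretical maximum solvent-accessible surface area per residue (Å²),
#: Tien et al. (2013) theoretical values; used to normalize absolute SASA.
MAX_ASA: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

_VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}

_FALLBACK = 0.5  # value a feature takes when its inputs cannot be used


class FeatureFailure(RuntimeError):
    """A feature could not be computed from the available inputs."""


@dataclass
class PredictionSet:
    """Per-target prediction inputs shared by all decoys of one target."""

    ss: Optional[SSPrediction] = None
    sa: Optional[SAPrediction] = None
    contacts: Optional[ContactPrediction] = None
    dope: dict[str, float] = field(default_factory=dict)
    goap: dict[str, float] = field(default_factory=dict)


@dataclass
class FeatureVector:
    """The six feature values for one model, in the canonical order.

    ``fallback_mask[k]`` is True where the k-th feature could not be computed
    and was set to the neutral fallback value 0.5.
    """

    e_dope: float
    e_goap: float
    e_ss_h: float
    e_ss_e: float
    e_sa: float
    e_contact: float
    fallback_mask: tuple[bool, bool, bool, bool, bool, bool] = (False,) * 6

    def as_array(self) -> np.ndarray:
        return np.array([self.e_dope, self.e_goap, self.e_ss_h,
                         self.e_ss_e, self.e_sa, self.e_contact])

    @classmethod
    def from_array(cls, values: Sequence[float],
                   fallback_mask: Sequence[bool] = (False,) * 6) -> "FeatureVector":
        v = list(map(float, values))
        if len(v) != 6:
            raise ValueError("feature vector needs exactly 6 values")
        return cls(*v, fallback_mask=tuple(bool(b) for b in fallback_mask))


# ---------------------------------------------------------------------------
# Binary XOR penalty

def binary_xor_penalty(x: str, p: str) -> float:
    """Fraction of positions where two equal-length binary strings differ.

    This is the penalty applied to every binarized channel: the parsed model
    property ``x`` against the sequence-based prediction ``p``.
    """
    if len(x) != len(p):
        raise ValueError(f"length mismatch: {len(x)} vs {len(p)}")
    if len(x) == 0:
        raise ValueError("empty strings have no defined penalty")
    a = np.frombuffer(x.encode(), dtype=np.uint8)
    b = np.frombuffer(p.encode(), dtype=np.uint8)
    return float(np.mean(a != b))


# ---------------------------------------------------------------------------
# Secondary structure (Kabsch–Sander)

_HB_ENERGY_CUTOFF = -0.5  # kcal/mol
_HB_Q1Q2_F = 0.084 * 332.0  # partial charges × electrostatic constant


def _backbone_arrays(model: ProteinModel):
    n = len(model)
    coords = {name: np.full((n, 3), np.nan) for name in ("N", "CA", "C", "O")}
    for i, res in enumerate(model.residues):
        for name in coords:
            if name in res.atoms:
                coords[name][i] = res.atoms[name]
    return coords


def _hbond_matrix(model: ProteinModel) -> np.ndarray:
    """hb[a, d] — the carbonyl of residue a accepts an H-bond from the NH of d.

    The amide hydrogen is reconstructed 1.0 Å from N along the preceding
    carbonyl C→O direction reversed (standard DSSP placement); the first
    residue of a chain segment and prolines cannot donate.
    """
    n = len(model)
    bb = _backbone_arrays(model)
    N, CA, C, O = bb["N"], bb["CA"], bb["C"], bb["O"]
    has_bb = np.all(np.isfinite(np.stack([N, CA, C, O], axis=1)), axis=(1, 2))

    # peptide-bond continuity between consecutive residues
    bonded = np.zeros(n, dtype=bool)  # bonded[i]: residue i-1 -- i
    for i in range(1, n):
        if np.all(np.isfinite(C[i - 1])) and np.all(np.isfinite(N[i])):
            bonded[i] = np.linalg.norm(C[i - 1] - N[i]) < 2.5

    H = np.full((n, 3), np.nan)
    for i in range(1, n):
        if not (bonded[i] and np.all(np.isfinite(O[i - 1]))):
            continue
        d = C[i - 1] - O[i - 1]
        nrm = np.linalg.norm(d)
        if nrm > 0:
            H[i] = N[i] + d / nrm

    can_donate = np.array([
        np.all(np.isfinite(H[i])) and model.residues[i].name != "PRO"
        for i in range(n)
    ])

    hb = np.zeros((n, n), dtype=bool)
    for a in range(n):
        if not has_bb[a]:
            continue
        for d in range(n):
            if abs(a - d) <= 1 or not can_donate[d] or not has_bb[d]:
                continue
            if np.linalg.norm(CA[a] - CA[d]) > 9.0:
                continue
            r_on = np.linalg.norm(O[a] - N[d])
            r_ch = np.linalg.norm(C[a] - H[d])
            r_oh = np.linalg.norm(O[a] - H[d])
            r_cn = np.linalg.norm(C[a] - N[d])
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                continue  # clashing geometry, no physical bond
            energy = _HB_Q1Q2_F * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
            if energy < _HB_ENERGY_CUTOFF:
                hb[a, d] = True
    return hb


def assign_secondary_structure(model: ProteinModel) -> str:
    """Three-state secondary structure (H/E/C) by hydrogen-bond patterns.

    Backbone H-bonds are assigned with the Kabsch–Sander electrostatic model
    (bond when E < −0.5 kcal/mol); α-helices from consecutive i→i+4 turns,
    strands from parallel/antiparallel bridge patterns, 3₁₀/π helices from
    i→i+3 / i→i+5 turns. The 8-state classes collapse as H,G,I→H; E,B→E;
    everything else →C. Residues with missing backbone atoms are C.
    """
    n = len(model)
    if n < 3:
        return "C" * n
    hb = _hbond_matrix(model)

    def turn(i: int, step: int) -> bool:
        return 0 <= i and i + step < n and hb[i, i + step]

    ss = ["C"] * n

    # alpha helix: two consecutive 4-turns mark residues i..i+3
    for i in range(1, n - 4):
        if turn(i - 1, 4) and turn(i, 4):
            for k in range(i, i + 4):
                ss[k] = "H"

    # bridges (beta): marked on residues not already helical
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            para = (hb[i - 1, j] and hb[j, i + 1]) or (hb[j - 1, i] and hb[i, j + 1])
            anti = (hb[i, j] and hb[j, i]) or (hb[i - 1, j + 1] and hb[j - 1, i + 1])
            if para or anti:
                if ss[i] == "C":
                    ss[i] = "E"
                if ss[j] == "C":
                    ss[j] = "E"

    # 3-10 and pi helices collapse to H on unassigned residues
    for step, span in ((3, 3), (5, 5)):
        for i in range(1, n - span):
            if turn(i - 1, step) and turn(i, step):
                for k in range(i, i + span):
                    if ss[k] == "C":
                        ss[k] = "H"

    return "".join(ss)


# ---------------------------------------------------------------------------
# Solvent-accessible surface area (Shrake–Rupley)

def _fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden-spiral)."""
    k = np.arange(n_points)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k
    z = 1.0 - (2.0 * k + 1.0) / n_points
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _element_of(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else ""


def compute_sasa(model: ProteinModel, probe_radius: float = 1.4,
                 n_points: int = 960) -> np.ndarray:
    """Per-residue absolute solvent-accessible surface area in Å².

    Shrake–Rupley sphere sampling over heavy atoms with a deterministic
    golden-spiral point set; per-atom areas are summed per residue.
    """
    if n_points < 92:
        raise ValueError("n_points must be at least 92 for a usable quadrature")
    coords: list[np.ndarray] = []
    radii: list[float] = []
    owner: list[int] = []
    for idx, res in enumerate(model.residues):
        for name, xyz in res.atoms.items():
            elem = _element_of(name)
            if elem == "H" or elem == "D":
                continue
            coords.append(xyz)
            radii.append(_VDW_RADII.get(elem, _VDW_RADII["C"]))
            owner.append(idx)
    areas = np.zeros(len(model))
    if not coords:
        warnings.warn("model has no heavy atoms; SASA is all zero")
        return areas
    xyz = np.asarray(coords)
    rad = np.asarray(radii) + probe_radius
    sphere = _fibonacci_sphere(n_points)
    tree = cKDTree(xyz)
    max_reach = 2.0 * rad.max()
    empty = np.zeros(len(model.residues))
    counts = np.zeros(len(model.residues))
    for a in range(len(xyz)):
        pts = xyz[a] + rad[a] * sphere
        neighbours = [b for b in tree.query_ball_point(xyz[a], max_reach) if b != a]
        accessible = np.ones(n_points, dtype=bool)
        for b in neighbours:
            d = np.linalg.norm(pts - xyz[b], axis=1)
            accessible &= d >= rad[b]
            if not accessible.any():
                break
        frac = accessible.mean()
        areas[owner[a]] += frac * 4.0 * math.pi * rad[a] ** 2
        counts[owner[a]] += 1
    for idx in np.nonzero(counts == 0)[0]:
        warnings.warn(f"residue {model.residues[idx].number} has no heavy atoms")
    return areas


def sa_binarize(abs_area: np.ndarray, model: ProteinModel,
                table: Optional[dict[str, float]] = None,
                threshold: float = 0.25) -> str:
    """Binarize per-residue SASA: '1' (exposed) where relative area ≥ threshold.

    Relative accessibility is the absolute area divided by the residue type's
    maximum exposed area; unknown residue names use the table mean. Ratios
    above 1 are simply exposed — no clipping error.
    """
    table = table if table is not None else MAX_ASA
    mean_max = float(np.mean(list(table.values())))
    if len(abs_area) != len(model.residues):
        raise ValueError("area vector does not match residue count")
    bits = []
    for area, res in zip(abs_area, model.residues):
        max_asa = table.get(res.name, mean_max)
        bits.append("1" if area / max_asa >= threshold else "0")
    return "".join(bits)


# ---------------------------------------------------------------------------
# Penalty terms

def ss_penalties(ss_model: str, ss_pred: SSPrediction | str) -> tuple[float, float]:
    """Helix and strand penalties: per-class binarized XOR disagreement."""
    pred = ss_pred.classes if isinstance(ss_pred, SSPrediction) else ss_pred
    if len(ss_model) != len(pred):
        raise ValueError("model and predicted secondary structure lengths differ")

    def channel(cls: str) -> float:
        x = "".join("1" if c == cls else "0" for c in ss_model)
        p = "".join("1" if c == cls else "0" for c in pred)
        return binary_xor_penalty(x, p)

    return channel("H"), channel("E")


def sa_penalty(sa_model: str, sa_pred: SAPrediction | str) -> float:
    """Solvent-accessibility penalty: XOR of binarized exposure strings."""
    if isinstance(sa_pred, SAPrediction):
        pred = sa_pred.as_binary()
    else:
        pred = sa_pred.translate(str.maketrans("eb", "10"))
    return binary_xor_penalty(sa_model, pred)


def contact_penalty(model: ProteinModel, contacts: ContactPrediction,
                    cutoff: float = 8.0) -> float:
    """Fraction of top-L predicted contacts violated by the model.

    Predictions are sorted by confidence (ties by ascending pair indices) and
    the first L usable pairs taken, L being the number of residues present in
    the model; pairs naming absent residues are skipped in favour of the next
    ones. A pair is satisfied when its reference atoms (Cβ; Cα for glycine or
    when Cβ is missing) lie within ``cutoff`` Å.
    """
    by_number: dict[int, np.ndarray] = {}
    for res in model.residues:
        ref = res.reference_atom()
        if ref is not None and res.number not in by_number:
            by_number[res.number] = ref
    L = len(model)
    taken = 0
    matched = 0
    for i, j, _conf in contacts.sorted_by_confidence():
        if taken >= L:
            break
        a, b = by_number.get(i), by_number.get(j)
        if a is None or b is None:
            continue
        taken += 1
        if np.linalg.norm(a - b) <= cutoff:
            matched += 1
    if taken == 0:
        raise FeatureFailure("no usable contact pairs for this model")
    return 1.0 - matched / taken


def normalize_potential(raw_score: float, n_res: int) -> float:
    """Normalize a DOPE/GOAP total by the number of residues."""
    if n_res < 1:
        raise ValueError("residue count must be at least 1")
    return raw_score / n_res


# ---------------------------------------------------------------------------
# Assembly

def _align_to_model(model: ProteinModel, pred: str) -> tuple[list[int], str]:
    """Indices of model residues whose number maps into the prediction string.

    Predictions are indexed by target-sequence position = PDB residue number
    (1-based); positions for residues absent from the model are dropped, and
    model residues outside the prediction are dropped from the comparison.
    """
    idx: list[int] = []
    chars: list[str] = []
    for k, res in enumerate(model.residues):
        pos = res.number
        if 1 <= pos <= len(pred):
            idx.append(k)
            chars.append(pred[pos - 1])
    return idx, "".join(chars)


def build_feature_vector(model: ProteinModel,
                         predictions: PredictionSet,
                         dope_raw: Optional[float] = None,
                         goap_raw: Optional[float] = None,
                         dssp: Optional[list[tuple[int, str, float]]] = None,
                         sasa_points: int = 960) -> FeatureVector:
    """Compute the six features for one model.

    Any feature whose inputs are missing or unusable falls back to the
    neutral value 0.5 and is flagged in ``fallback_mask``. When a parsed DSSP
    file is supplied its secondary structure and absolute accessibilities are
    used for the model; otherwise both are computed internally.
    """
    n = len(model)
    values: list[float] = []
    mask: list[bool] = []

    def with_fallback(fn) -> None:
        try:
            values.append(float(fn()))
            mask.append(False)
        except (FeatureFailure, ValueError, KeyError, TypeError):
            values.append(_FALLBACK)
            mask.append(True)

    if dope_raw is None:
        dope_raw = predictions.dope.get(model.model_id)
    if goap_raw is None:
        goap_raw = predictions.goap.get(model.model_id)

    with_fallback(lambda: normalize_potential(_require(dope_raw, "DOPE"), n))
    with_fallback(lambda: normalize_potential(_require(goap_raw, "GOAP"), n))

    # model-side secondary structure and accessibility
    if dssp is not None:
        by_number = {num: (ss, acc) for num, ss, acc in dssp}
        ss_model_full = "".join(by_number.get(r.number, ("C",))[0]
                                for r in model.residues)
        acc_full = np.array([by_number.get(r.number, ("C", 0.0))[1]
                             for r in model.residues])
    else:
        ss_model_full = assign_secondary_structure(model)
        acc_full = None  # computed lazily, only if an SA prediction exists

    def ss_pair():
        if predictions.ss is None:
            raise FeatureFailure("no secondary-structure prediction")
        idx, pred = _align_to_model(model, predictions.ss.classes)
        if not idx:
            raise FeatureFailure("prediction does not cover any model residue")
        ss_model = "".join(ss_model_full[k] for k in idx)
        return ss_penalties(ss_model, pred)

    try:
        e_h, e_e = ss_pair()
        values.extend([e_h, e_e])
        mask.extend([False, False])
    except (FeatureFailure, ValueError):
        values.extend([_FALLBACK, _FALLBACK])
        mask.extend([True, True])

    def sa_term() -> float:
        if predictions.sa is None:
            raise FeatureFailure("no solvent-accessibility prediction")
        idx, pred = _align_to_model(model, predictions.sa.classes)
        if not idx:
            raise FeatureFailure("prediction does not cover any model residue")
        areas = acc_full if acc_full is not None else compute_sasa(
            model, n_points=sasa_points)
        sa_model_full = sa_binarize(areas, model)
        sa_model = "".join(sa_model_full[k] for k in idx)
        return sa_penalty(sa_model, SAPrediction("".join(pred)))

    with_fallback(sa_term)

    def contact_term() -> float:
        if predictions.contacts is None:
            raise FeatureFailure("no contact prediction")
        return contact_penalty(model, predictions.contacts)

    with_fallback(contact_term)

    return FeatureVector(*values, fallback_mask=tuple(mask))


def _require(value: Optional[float], label: str) -> float:
    if value is None:
        raise FeatureFailure(f"missing {label} score")
    return float(value)
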