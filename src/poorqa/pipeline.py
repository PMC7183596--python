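"""Glue between the on-disk fixture-tree layout and the in-memory pipeline.

A tree holds one directory of PDB decoys per target plus sibling prediction
files: ``{target}/{model}.pdb``, ``{target}.ss``, ``{target}.acc``,
``{target}.rr`` and ``{target}.scores``. Model ids are PDB basenames without
extension, which is also how score-table rows are matched to files.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional

import pandas as pd

from .features import PredictionSet, build_feature_vector
from .scoring import PoolModel, TargetPool, WeightVector
from .structure_io import (
    FormatError,
    QualityTable,
    read_contact_rr,
    read_pdb,
    read_sa_prediction,
    read_score_table,
    read_ss_prediction,
)

__all__ = ["discover_targets", "load_predictions", "build_target_pool",
           "load_tree", "pool_table", "pools_from_table"]


def discover_targets(root: str | Path) -> list[str]:
    """Target ids = subdirectories of the tree that contain PDB files."""
    root = Path(root)
    return sorted(d.name for d in root.iterdir()
                  if d.is_dir() and any(d.glob("*.pdb")))


def load_predictions(root: str | Path, target_id: str,
                     n_res: int) -> PredictionSet:
    """Load whichever prediction files exist for a target; missing ones stay
    None and trigger the 0.5 feature fallback downstream."""
    root = Path(root)
    preds = PredictionSet()
    ss_path = root / f"{target_id}.ss"
    if ss_path.exists():
        preds.ss = read_ss_prediction(ss_path)
    sa_path = root / f"{target_id}.acc"
    if sa_path.exists():
        preds.sa = read_sa_prediction(sa_path)
    rr_path = root / f"{target_id}.rr"
    if rr_path.exists():
        try:
            preds.contacts = read_contact_rr(rr_path, n_res)
        except FormatError as exc:
            warnings.warn(str(exc))
    scores_path = root / f"{target_id}.scores"
    if scores_path.exists():
        df = pd.read_csv(scores_path, sep=None, engine="python")
        if "dope" in df.columns:
            preds.dope = dict(zip(df["model"].astype(str), df["dope"]))
        if "goap" in df.columns:
            preds.goap = dict(zip(df["model"].astype(str), df["goap"]))
    return preds


def build_target_pool(root: str | Path, target_id: str,
                      pred_root: Optional[str | Path] = None,
                      sasa_points: int = 240,
                      with_labels: bool = True) -> TargetPool:
    """Read one target's decoys, compute the six features, attach labels."""
    root = Path(root)
    pred_root = Path(pred_root) if pred_root is not None else root
    pdb_paths = sorted((root / target_id).glob("*.pdb"))
    if not pdb_paths:
        raise FormatError(f"no PDB decoys under {root / target_id}")
    quality: Optional[QualityTable] = None
    scores_path = pred_root / f"{target_id}.scores"
    if with_labels and scores_path.exists():
        quality = read_score_table(scores_path)
    models = []
    preds: Optional[PredictionSet] = None
    for path in pdb_paths:
        model = read_pdb(path)
        if preds is None:
            preds = load_predictions(pred_root, target_id,
                                     max(model.residue_numbers))
        fv = build_feature_vector(model, preds, sasa_points=sasa_points)
        gdt = tm = None
        if quality is not None and model.model_id in quality.entries:
            gdt = quality.gdt_ts(model.model_id)
            tm = quality.tm_score(model.model_id)
        models.append(PoolModel(model_id=model.model_id, features=fv,
                                gdt_ts=gdt, tm_score=tm))
    return TargetPool(target_id=target_id, models=models)


def load_tree(root: str | Path, pred_root: Optional[str | Path] = None,
              sasa_points: int = 240,
              with_labels: bool = True) -> list[TargetPool]:
    """Feature-compute every target pool in a fixture tree."""
    return [build_target_pool(root, t, pred_root=pred_root,
                              sasa_points=sasa_points, with_labels=with_labels)
            for t in discover_targets(root)]


def pool_table(pools: list[TargetPool],
               weights: Optional[WeightVector] = None) -> pd.DataFrame:
    """Flatten pools into the feature/ranking table the CLI writes.

    Columns: target_id, model_id, optional rank and score E, the six
    features, the six fallback flags, and labels where present.
    """
    from .features import FEATURE_NAMES
    from .scoring import combine, rank_pool

    rows = []
    for pool in pools:
        ranks = {}
        if weights is not None:
            ranks = {m.model_id: r + 1
                     for r, m in enumerate(rank_pool(pool, weights))}
        for m in pool.models:
            row: dict = {"target_id": pool.target_id, "model_id": m.model_id}
            if weights is not None:
                row["rank"] = ranks[m.model_id]
                row["E"] = combine(m.features, weights)
            for name, value in zip(FEATURE_NAMES, m.features.as_array()):
                row[f"e_{name}"] = value
            for name, flag in zip(FEATURE_NAMES, m.features.fallback_mask):
                row[f"fallback_{name}"] = int(flag)
            if m.gdt_ts is not None:
                row["gdt_ts"] = m.gdt_ts
            if m.tm_score is not None:
                row["tm_score"] = m.tm_score
            rows.append(row)
    df = pd.DataFrame(rows)
    if weights is not None:
        df = df.sort_values(["target_id", "rank"]).reset_index(drop=True)
    return df


def pools_from_table(df: pd.DataFrame,
                     quality: Optional[pd.DataFrame] = None) -> list[TargetPool]:
    """Rebuild TargetPools from a feature table (and an optional quality join)."""
    from .features import FEATURE_NAMES, FeatureVector

    if quality is not None:
        q = quality.copy()
        if "gdt_ts" in df.columns:
            df = df.drop(columns=[c for c in ("gdt_ts", "tm_score")
                                  if c in df.columns])
        df = df.merge(q, left_on="model_id", right_on="model", how="left")
    pools = []
    for target_id, group in df.groupby("target_id", sort=True):
        models = []
        for _, row in group.iterrows():
            fv = FeatureVector.from_array(
                [row[f"e_{name}"] for name in FEATURE_NAMES])
            gdt = row.get("gdt_ts")
            if gdt is not None and pd.notna(gdt):
                gdt = float(gdt)
                if gdt <= 1.0:
                    gdt *= 100.0
            else:
                gdt = None
            tm = row.get("tm_score")
            tm = float(tm) if tm is not None and pd.notna(tm) else None
            models.append(PoolModel(model_id=str(row["model_id"]),
                                    features=fv, gdt_ts=gdt, tm_score=tm))
        pools.append(TargetPool(target_id=str(target_id), models=models))
    return pools
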