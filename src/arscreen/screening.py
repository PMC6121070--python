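"""Staged virtual-screening cascade.

Stages, in order: Lipinski rule-of-five filter -> descriptor computation ->
prediction with the four scoring equations -> consensus activity threshold
(all four predicted pIC50 above the cutoff) -> scaffold substructure
restriction -> optional merge of externally produced docking scores ->
deterministic ranking.  Every input molecule ends in exactly one terminal
category: ranked, or excluded with a recorded reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from rdkit import Chem

from . import descriptors as desc_mod
from . import qsar
from .chemio import Molecule, read_molecules
from .topo import lipinski_properties

logger = logging.getLogger(__name__)

#: fused pyrazolo[1,5-a]pyrimidine bicycle — the hit chemotype's skeleton
PYRAZOLOPYRIMIDINE_SMARTS = "c1cnc2ccnn2c1"

#: rule-of-five thresholds; comparisons are strict (<) as published
LIPINSKI_LIMITS = {"HBD": 5, "HBA": 10, "MW": 500.0, "AlogP": 5.0}


class CascadeError(RuntimeError):
    pass


@dataclass
class ScreeningRecord:
    """Per-molecule ledger of stage outcomes."""

    mol_id: str
    smiles: str = ""
    lipinski_pass: bool | None = None
    lipinski_reasons: tuple[str, ...] = ()
    predictions: dict = field(default_factory=dict)   # model name -> pIC50
    consensus_pass: bool | None = None
    substructure_pass: bool | None = None
    docking_score: float | None = None
    rank: int | None = None
    stage_reached: str = "input"
    exclusion_reason: str = ""


def lipinski_filter(mols: list[Molecule]) -> tuple[list[Molecule], list[tuple[Molecule, list[str]]]]:
    """Partition by the rule of five; failures carry every violated rule."""
    passed, failed = [], []
    for mol in mols:
        props = lipinski_properties(mol)
        reasons = []
        if not props.hbd < LIPINSKI_LIMITS["HBD"]:
            reasons.append("HBD")
        if not props.hba < LIPINSKI_LIMITS["HBA"]:
            reasons.append("HBA")
        if not props.mw < LIPINSKI_LIMITS["MW"]:
            reasons.append("MW")
        if not props.alogp < LIPINSKI_LIMITS["AlogP"]:
            reasons.append("AlogP")
        (failed.append((mol, reasons)) if reasons else passed.append(mol))
    return passed, failed


def consensus_filter(predictions: pd.DataFrame, threshold: float = 7.0) -> pd.Series:
    """Boolean retain mask: all model predictions strictly above threshold.

    Rows with any NaN prediction are never retained.
    """
    return predictions.gt(threshold).all(axis=1) & predictions.notna().all(axis=1)


def substructure_filter(mols: list[Molecule], query: str = PYRAZOLOPYRIMIDINE_SMARTS
                        ) -> tuple[list[Molecule], list[Molecule]]:
    """Partition a molecule list by SMARTS substructure match."""
    patt = Chem.MolFromSmarts(query)
    if patt is None:
        raise CascadeError(f"invalid SMARTS query: {query!r}")
    match = [m for m in mols if m.heavy.HasSubstructMatch(patt)]
    rest = [m for m in mols if not m.heavy.HasSubstructMatch(patt)]
    return match, rest


def read_docking_scores(path: str | Path) -> pd.Series:
    """Docking-score CSV (columns id, score); more negative = better affinity."""
    df = pd.read_csv(path)
    if not {"id", "score"} <= set(df.columns):
        raise CascadeError(f"{path}: docking CSV needs columns id,score")
    ids = df["id"].astype(str)
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise CascadeError(f"{path}: duplicate docking ids {dupes}")
    return pd.Series(df["score"].to_numpy(dtype=float), index=ids, name="docking_score")


def merge_docking_scores(records: list[ScreeningRecord], scores: pd.Series) -> list[ScreeningRecord]:
    """Left-join docking scores onto records by molecule id; log misses."""
    rec_ids = {r.mol_id for r in records}
    for r in records:
        if r.mol_id in scores.index:
            r.docking_score = float(scores[r.mol_id])
        else:
            logger.info("no docking score for %s", r.mol_id)
    for sid in scores.index:
        if sid not in rec_ids:
            logger.info("docking score for unknown id %s", sid)
    return records


RANK_MODES = ("consensus_min", "consensus_mean", "docking_then_qsar")


def rank_hits(records: list[ScreeningRecord], mode: str = "consensus_min") -> list[ScreeningRecord]:
    """Assign 1-based ranks with a deterministic total order.

    ``consensus_min`` sorts by the worst of the four predictions (descending),
    ``consensus_mean`` by their mean, ``docking_then_qsar`` by docking score
    (ascending: more negative is better) then min-prediction.  Ties break on
    molecule id, lexicographically.
    """
    if mode not in RANK_MODES:
        raise ValueError(f"unknown ranking mode {mode!r}")

    def key(r: ScreeningRecord):
        preds = list(r.predictions.values())
        if mode == "consensus_min":
            return (-min(preds), r.mol_id)
        if mode == "consensus_mean":
            return (-sum(preds) / len(preds), r.mol_id)
        dock = r.docking_score if r.docking_score is not None else float("inf")
        return (dock, -min(preds), r.mol_id)

    for i, r in enumerate(sorted(records, key=key), start=1):
        r.rank = i
    return sorted(records, key=lambda r: r.rank)


@dataclass(frozen=True)
class CascadeConfig:
    """Everything one cascade run needs; all seeds and thresholds explicit."""

    library: str | Path | list[Molecule]
    models: list[qsar.LinearModel] | None = None     # default: the 4 published
    threshold: float = 7.0
    substructure: str | None = PYRAZOLOPYRIMIDINE_SMARTS
    docking_csv: str | Path | None = None
    rank_mode: str = "consensus_min"
    seed: int = 2018


@dataclass
class CascadeResult:
    records: list[ScreeningRecord]
    stage_counts: dict[str, int]
    stopped_at: str | None = None

    def table(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "id": r.mol_id, "smiles": r.smiles,
                "lipinski_pass": r.lipinski_pass,
                "consensus_pass": r.consensus_pass,
                "substructure_pass": r.substructure_pass,
                "docking_score": r.docking_score, "rank": r.rank,
                "stage_reached": r.stage_reached,
                "exclusion_reason": r.exclusion_reason,
            }
            for m, v in r.predictions.items():
                row[m] = v
            rows.append(row)
        return pd.DataFrame(rows)

    def summary_text(self) -> str:
        lines = ["stage counts (survivors after each stage):"]
        for stage, n in self.stage_counts.items():
            lines.append(f"  {stage:<14} {n}")
        if self.stopped_at:
            lines.append(f"pipeline stopped at stage {self.stopped_at!r}: zero survivors")
        return "\n".join(lines)


def run_cascade(config: CascadeConfig) -> CascadeResult:
    """Execute the full staged screening cascade.

    Stage order: input -> lipinski -> descriptors -> consensus ->
    substructure -> docking merge -> rank.  Survivor counts are monotone
    non-increasing; a stage with zero survivors stops the pipeline with an
    informative summary.
    """
    if isinstance(config.library, (str, Path)):
        mols = read_molecules(config.library)
    else:
        mols = list(config.library)
    if not mols:
        raise CascadeError("empty molecule library")
    models = config.models if config.models is not None else qsar.published_models()

    records = {m.mol_id: ScreeningRecord(m.mol_id, smiles=m.smiles()) for m in mols}
    counts: dict[str, int] = {"input": len(mols)}

    # Lipinski
    passed, failed = lipinski_filter(mols)
    for mol, reasons in failed:
        r = records[mol.mol_id]
        r.lipinski_pass = False
        r.lipinski_reasons = tuple(reasons)
        r.stage_reached = "lipinski"
        r.exclusion_reason = "lipinski:" + "+".join(reasons)
    for mol in passed:
        records[mol.mol_id].lipinski_pass = True
    counts["lipinski"] = len(passed)
    if not passed:
        return CascadeResult(list(records.values()), counts, stopped_at="lipinski")

    # descriptors + predictions
    needed = sorted({d for m in models for d in m.descriptor_ids})
    values, reasons_df = desc_mod.compute_matrix(passed, needed, seed=config.seed)
    preds = pd.DataFrame({m.name: qsar.predict_frame(m, values) for m in models})
    predictable = preds.notna().all(axis=1)
    for mid in preds.index[~predictable]:
        r = records[mid]
        missing = [c for c in needed if reasons_df.loc[mid, c]]
        r.stage_reached = "descriptors"
        r.exclusion_reason = "descriptors-missing:" + "+".join(
            f"{c}({reasons_df.loc[mid, c]})" for c in missing)
    counts["descriptors"] = int(predictable.sum())
    survivors = [m for m in passed if predictable[m.mol_id]]
    for m in survivors:
        records[m.mol_id].predictions = preds.loc[m.mol_id].to_dict()
    if not survivors:
        return CascadeResult(list(records.values()), counts, stopped_at="descriptors")

    # consensus
    retain = consensus_filter(preds.loc[[m.mol_id for m in survivors]], config.threshold)
    for m in survivors:
        r = records[m.mol_id]
        r.consensus_pass = bool(retain[m.mol_id])
        if not r.consensus_pass:
            r.stage_reached = "consensus"
            low = [k for k, v in r.predictions.items() if not v > config.threshold]
            r.exclusion_reason = "consensus:" + "+".join(low)
    survivors = [m for m in survivors if retain[m.mol_id]]
    counts["consensus"] = len(survivors)
    if not survivors:
        return CascadeResult(list(records.values()), counts, stopped_at="consensus")

    # substructure
    if config.substructure is not None:
        hits, rest = substructure_filter(survivors, config.substructure)
        for m in rest:
            r = records[m.mol_id]
            r.substructure_pass = False
            r.stage_reached = "substructure"
            r.exclusion_reason = "substructure"
        for m in hits:
            records[m.mol_id].substructure_pass = True
        survivors = hits
        counts["substructure"] = len(survivors)
        if not survivors:
            return CascadeResult(list(records.values()), counts, stopped_at="substructure")

    # docking merge (optional) + rank
    final = [records[m.mol_id] for m in survivors]
    if config.docking_csv is not None:
        merge_docking_scores(final, read_docking_scores(config.docking_csv))
    rank_hits(final, config.rank_mode)
    for r in final:
        r.stage_reached = "ranked"
    counts["ranked"] = len(final)
    return CascadeResult(list(records.values()), counts)
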