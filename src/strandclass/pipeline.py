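"""End-to-end orchestration: extract, select, train, evaluate, predict.

The full feature vector of one protein concatenates seven blocks in a fixed,
documented order (column indices are therefore stable across runs):

    OAAC (20) | dipeptide (1200) | PSSM-ACC (100) | AAindex-ACC (140)
    | DisEMBL-ACC (15) | NetSurfP-ACC (30) | LSE-ACC (5)   -> 1510 columns

with the defaults: gaps {0,1,2}, 28-property physicochemical table, maximum
lag 5, autocovariance only.  Profile-derived blocks need per-protein profile
files (PSI-BLAST PSSM, NetSurfP, DisEMBL dialects); proteins missing any
enabled input, or too short for an enabled extractor, are excluded
dataset-wide and listed in an exclusion manifest — a partially filled feature
row would be meaningless to the classifier.

Train/test hygiene: selection and fitting happen on training data only; the
retained-column list and the fitted model are persisted and re-applied
verbatim to evaluation data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import io as sio
from .acc import ACCConfig, acc as acc_transform
from .features import (
    default_lse_table,
    default_property_table,
    dipeptide,
    lse_profile,
    oaac,
    physicochemical_profile,
)
from .model import (
    EvalReport,
    ModelConfig,
    TrainedModel,
    compute_metrics,
    cross_validate,
    grid_search,
    predict as model_predict,
    train_final,
)
from .select import relevance_scores, threshold_select, threshold_sweep
from .types import (
    FeatureBlock,
    FeatureMatrix,
    PropertyTable,
    ProteinRecord,
    ResidueProfile,
    StrandclassError,
    matrix_from_blocks,
)

logger = logging.getLogger(__name__)

#: Fixed block concatenation order.
BLOCK_ORDER: Tuple[str, ...] = (
    "OAAC", "dipeptide", "PSSM", "AAindex", "DisEMBL", "NetSurfP", "LSE",
)

#: Blocks that require an external per-protein profile file.
PROFILE_BLOCKS = {"PSSM": "pssm", "DisEMBL": "disembl", "NetSurfP": "netsurfp"}

#: Default relevance threshold for the final feature subset.
DEFAULT_THRESHOLD = 0.005


@dataclass
class ExtractConfig:
    """What to extract and with which settings.

    ``blocks`` toggles extractors (default: all seven); profile blocks read
    ``<profile_dir>/<kind>/<protein_id>.<ext>`` files.  The physicochemical
    and 4-mer tables default to the shipped stand-ins and are replaceable.
    """

    blocks: Tuple[str, ...] = BLOCK_ORDER
    oaac_mode: str = "sqrt_frequency"
    gaps: Tuple[int, ...] = (0, 1, 2)
    acc: ACCConfig = field(default_factory=ACCConfig)
    property_table: Optional[PropertyTable] = None
    lse_table: Optional[PropertyTable] = None
    profile_dir: Optional[Path] = None

    def __post_init__(self) -> None:
        unknown = [b for b in self.blocks if b not in BLOCK_ORDER]
        if unknown:
            raise StrandclassError(f"unknown feature blocks: {unknown}")
        if any(b in PROFILE_BLOCKS for b in self.blocks) and self.profile_dir is None:
            raise StrandclassError(
                "profile-derived blocks enabled but no profile_dir given"
            )


_PROFILE_EXT = {"pssm": "pssm", "netsurfp": "netsurfp.tsv", "disembl": "disembl.tsv"}


def _load_profile(kind: str, directory: Path, protein_id: str) -> ResidueProfile:
    path = directory / kind / f"{protein_id}.{_PROFILE_EXT[kind]}"
    if not path.exists():
        raise StrandclassError(f"missing {kind} profile for {protein_id!r}: {path}")
    if kind == "pssm":
        return sio.read_pssm(path, protein_id=protein_id)
    return sio.read_residue_table(path, format=kind, protein_id=protein_id)


def _acc_block(name: str, profile: ResidueProfile, config: ACCConfig) -> FeatureBlock:
    inner = acc_transform(profile, config)
    return FeatureBlock(source=name, labels=inner.labels, values=inner.values)


def extract_blocks(
    record: ProteinRecord, config: ExtractConfig
) -> List[FeatureBlock]:
    """All enabled feature blocks for one protein, in the fixed order.

    Raises (naming the protein) when the sequence is too short for an enabled
    extractor or a required profile file is missing.
    """
    prop_table = config.property_table or default_property_table()
    blocks: List[FeatureBlock] = []
    for name in BLOCK_ORDER:
        if name not in config.blocks:
            continue
        if name == "OAAC":
            blocks.append(oaac(record, mode=config.oaac_mode))
        elif name == "dipeptide":
            blocks.append(dipeptide(record, gaps=config.gaps))
        elif name in PROFILE_BLOCKS:
            profile = _load_profile(
                PROFILE_BLOCKS[name], Path(config.profile_dir), record.id
            )
            if profile.length != len(record.sequence):
                raise StrandclassError(
                    f"protein {record.id!r}: {name} profile length "
                    f"{profile.length} != sequence length {len(record.sequence)}"
                )
            blocks.append(_acc_block(name, profile, config.acc))
        elif name == "AAindex":
            blocks.append(
                _acc_block(name, physicochemical_profile(record, prop_table), config.acc)
            )
        elif name == "LSE":
            table = config.lse_table or _shared_lse_table()
            blocks.append(_acc_block(name, lse_profile(record, table), config.acc))
    return blocks


_LSE_CACHE: Dict[str, PropertyTable] = {}


def _shared_lse_table() -> PropertyTable:
    # the default 4-mer table enumerates 160k entries; build it once
    if "default" not in _LSE_CACHE:
        _LSE_CACHE["default"] = default_lse_table()
    return _LSE_CACHE["default"]


def extract_features(
    records: Sequence[ProteinRecord],
    labels: Sequence[str],
    config: Optional[ExtractConfig] = None,
) -> Tuple[FeatureMatrix, Dict[str, str]]:
    """Feature matrix over a dataset, plus the exclusion manifest.

    Proteins failing any enabled extractor are dropped with a logged warning
    and recorded as ``{protein_id: reason}``.  Raises if no protein survives.
    """
    config = config or ExtractConfig(
        blocks=tuple(b for b in BLOCK_ORDER if b not in PROFILE_BLOCKS)
    )
    kept_ids: List[str] = []
    kept_labels: List[str] = []
    rows: List[List[FeatureBlock]] = []
    excluded: Dict[str, str] = {}
    for rec, lab in zip(records, labels):
        try:
            rows.append(extract_blocks(rec, config))
        except StrandclassError as exc:
            excluded[rec.id] = str(exc)
            logger.warning("excluding %r: %s", rec.id, exc)
            continue
        kept_ids.append(rec.id)
        kept_labels.append(lab)
    if not kept_ids:
        raise StrandclassError("no usable proteins after extraction")
    return matrix_from_blocks(kept_ids, kept_labels, rows), excluded


@dataclass
class SelectArtifacts:
    matrix: FeatureMatrix
    columns: List[str]
    relevance: Dict[str, float]
    sweep: List[Tuple[float, int]]


def select_features(
    matrix: FeatureMatrix,
    threshold: float = DEFAULT_THRESHOLD,
    sweep_thresholds: Sequence[float] = (0.0, 0.001, 0.005, 0.01, 0.05, 0.1),
) -> SelectArtifacts:
    """Relevance-threshold selection plus the sweep table for diagnostics.

    Raises when the threshold retains nothing (the sweep is still computed so
    callers can report it)."""
    rel = relevance_scores(matrix)
    sweep = [
        (float(t), sum(1 for v in rel.values() if v > t)) for t in sweep_thresholds
    ]
    sel = threshold_select(matrix, threshold, relevance=rel)
    if sel.retained == 0:
        raise StrandclassError(
            f"relevance threshold {threshold} retains no columns "
            f"(max relevance {max(rel.values()):.4f})"
        )
    return SelectArtifacts(
        matrix=sel.matrix, columns=list(sel.matrix.columns), relevance=rel, sweep=sweep
    )


@dataclass
class TrainArtifacts:
    model: TrainedModel
    config: ModelConfig
    cv_report: EvalReport


def train_pipeline(
    matrix: FeatureMatrix,
    config: Optional[ModelConfig] = None,
    folds: int = 10,
    do_grid_search: bool = False,
) -> TrainArtifacts:
    """Optionally grid-search hyperparameters, cross-validate, fit on all data."""
    config = config or ModelConfig()
    if do_grid_search:
        config, _ = grid_search(matrix, config, folds=folds)
    report = cross_validate(matrix, config, folds=folds)
    model = train_final(matrix, config)
    return TrainArtifacts(model=model, config=config, cv_report=report)


def evaluate_independent(
    model: TrainedModel, matrix: FeatureMatrix, columns: Sequence[str]
) -> EvalReport:
    """Score an independent labelled set with a trained model.

    The persisted training column list is applied verbatim — no re-selection
    or re-fitting happens on the evaluation data.
    """
    sub = matrix.subset_columns(list(columns))
    scores, labels = model_predict(model, sub)
    pred = np.array([1 if l == "SSB" else 0 for l in labels])
    return compute_metrics(sub.y(), pred, scores)


def write_report(report: EvalReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
        fh.write("\n")
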