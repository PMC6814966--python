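"""Binding-preference classification and agreement scoring.

For each interactor, one docking model per ATXN1 variant is selected
(lowest cluster Z-score, or highest interaction probability), interface
metrics are computed for both complexes, and the interactor is classified
as preferring the expanded variant if the chosen metric is larger for the
Q82 dock, the wild type if smaller, and "no preference" on equality.
Predicted labels are then cross-tabulated against experimentally
determined preferences (the quantitative yeast two-hybrid screen of
Suter et al. 2013 for the 71 ATXN1 partners shipped as package data).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .interface import residue_delta_asa
from .structure import assign_vdw_radii, read_pdb

logger = logging.getLogger(__name__)

__all__ = [
    "DockRecord",
    "PreferenceRecord",
    "AgreementSummary",
    "ComparisonResult",
    "METRIC_NAMES",
    "PREFERENCE_LABELS",
    "select_docking_model",
    "classify_preference",
    "score_agreement",
    "derive_method1_predictions",
    "derive_method2_predictions",
    "methodology_concordance",
    "load_methodology_table",
    "load_validation_table",
    "run_full_comparison",
]

METRIC_NAMES = (
    "n_interface_receptor",
    "pct_interface_receptor",
    "n_interface_partner",
    "pct_interface_partner",
    "buried_area",
    "pct_buried_area",
)
DEFAULT_METRIC = "n_interface_receptor"
PREFERENCE_LABELS = ("wt", "expanded", "no_preference")

#: Equality tolerance per metric: exact for counts, 0.05 for float areas/percentages.
_METRIC_TOLERANCE = {
    "n_interface_receptor": 0.0,
    "n_interface_partner": 0.0,
    "pct_interface_receptor": 0.05,
    "pct_interface_partner": 0.05,
    "buried_area": 0.05,
    "pct_buried_area": 0.05,
}

VARIANTS = ("wt_Q29", "expanded_Q82")


@dataclass
class DockRecord:
    """One docking model's metadata for a given (interactor, variant)."""

    interactor_id: str
    variant: str
    model_id: str
    scores: dict[str, float]
    structure_path: str


def select_docking_model(
    records: Sequence[DockRecord],
    criterion: str = "lowest_zscore",
    probability_field: str = "probability",
) -> DockRecord:
    """Pick one model: argmin of Z-score or argmax of the probability field.

    Ties are broken by the lexicographically first model_id (logged).
    """
    if not records:
        raise ValueError("no docking records to select from")
    if criterion == "lowest_zscore":
        score_field, sign = "zscore", 1.0
    elif criterion == "max_probability":
        score_field, sign = probability_field, -1.0
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    for rec in records:
        if score_field not in rec.scores:
            raise KeyError(
                f"record {rec.interactor_id}/{rec.model_id} lacks score field {score_field!r}"
            )
    ordered = sorted(records, key=lambda r: (sign * r.scores[score_field], r.model_id))
    best = ordered[0]
    if len(ordered) > 1 and ordered[1].scores[score_field] == best.scores[score_field]:
        logger.info(
            "tie on %s for %s; keeping first model_id %s",
            score_field,
            best.interactor_id,
            best.model_id,
        )
    return best


def classify_preference(value_wt: float, value_exp: float, tolerance: float = 0.0) -> str:
    """Greater metric for the expanded dock → 'expanded'; smaller → 'wt';
    equal (within ``tolerance``) → 'no_preference'."""
    if math.isnan(value_wt) or math.isnan(value_exp):
        raise ValueError("cannot classify NaN metric values")
    if abs(value_exp - value_wt) <= tolerance:
        return "no_preference"
    return "expanded" if value_exp > value_wt else "wt"


@dataclass
class PreferenceRecord:
    interactor_id: str
    metric_name: str
    value_wt: float
    value_exp: float
    predicted: str
    experimental: str = "unknown"


@dataclass
class AgreementSummary:
    """Cross-tabulation of predicted vs experimental preference labels."""

    crosstab: dict[tuple[str, str], int]
    n_total: int
    n_agree: int
    pct_agree: float
    per_class: dict[str, tuple[int, int, float]]  # experimental label -> (n, n same, pct)

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_agree": self.n_agree,
            "pct_agree": self.pct_agree,
            "crosstab": {f"{p}|{e}": c for (p, e), c in sorted(self.crosstab.items())},
            "per_class": {
                label: {"n": n, "n_agree": k, "pct": pct}
                for label, (n, k, pct) in sorted(self.per_class.items())
            },
        }

    def format_crosstab(self) -> str:
        preds = sorted({p for p, _ in self.crosstab})
        exps = sorted({e for _, e in self.crosstab})
        width = max(14, *(len(x) for x in preds + exps))
        lines = ["predicted \\ experimental".ljust(26) + "".join(e.rjust(width + 2) for e in exps)]
        for p in preds:
            row = p.ljust(26) + "".join(
                str(self.crosstab.get((p, e), 0)).rjust(width + 2) for e in exps
            )
            lines.append(row)
        lines.append(f"agreement: {self.n_agree}/{self.n_total} ({self.pct_agree}%)")
        return "\n".join(lines)


def score_agreement(
    predicted: Mapping[str, str], experimental: Mapping[str, str]
) -> AgreementSummary:
    """Overall and per-experimental-class agreement of two label maps.

    Keys must match exactly; percentages are rounded to one decimal.
    """
    if set(predicted) != set(experimental):
        diff = sorted(set(predicted) ^ set(experimental))
        raise ValueError(f"interactor sets differ; symmetric difference: {diff}")
    crosstab: dict[tuple[str, str], int] = {}
    n_agree = 0
    for key, pred in predicted.items():
        exp = experimental[key]
        crosstab[(pred, exp)] = crosstab.get((pred, exp), 0) + 1
        if pred == exp:
            n_agree += 1
    n_total = len(predicted)
    per_class: dict[str, tuple[int, int, float]] = {}
    for label in sorted({e for e in experimental.values() if e != "unknown"}):
        n_class = sum(1 for e in experimental.values() if e == label)
        n_same = crosstab.get((label, label), 0)
        per_class[label] = (n_class, n_same, round(100.0 * n_same / n_class, 1))
    return AgreementSummary(
        crosstab=crosstab,
        n_total=n_total,
        n_agree=n_agree,
        pct_agree=round(100.0 * n_agree / n_total, 1) if n_total else 0.0,
        per_class=per_class,
    )


# Methodology categories: how the two selection criteria labelled each
# interactor.  Approach 1 = lowest Z-score; approach 2 = highest
# interaction probability.  "wt_1_expanded_1_and_2" marks the one
# interactor called wt by approach 1 in one dock but expanded by both
# approaches elsewhere; its approach-1 call resolves to wt.
_CATEGORY_TO_APPROACH1 = {
    "wt_in_both": "wt",
    "expanded_in_both": "expanded",
    "wt_1_expanded_2": "wt",
    "wt_2_expanded_1": "expanded",
    "wt_1_expanded_1_and_2": "wt",
}
_CATEGORY_TO_APPROACH2 = {
    "wt_in_both": "wt",
    "expanded_in_both": "expanded",
    "wt_1_expanded_2": "expanded",
    "wt_2_expanded_1": "wt",
    "wt_1_expanded_1_and_2": "expanded",
}


def _derive(categories: Mapping[str, str], table: Mapping[str, str]) -> dict[str, str]:
    out = {}
    for key, cat in categories.items():
        if cat not in table:
            raise ValueError(f"unknown methodology category {cat!r} for {key}")
        out[key] = table[cat]
    return out


def derive_method1_predictions(categories: Mapping[str, str]) -> dict[str, str]:
    """Approach-1 (lowest Z-score) preference label per interactor."""
    return _derive(categories, _CATEGORY_TO_APPROACH1)


def derive_method2_predictions(categories: Mapping[str, str]) -> dict[str, str]:
    """Approach-2 (highest interaction probability) preference label."""
    return _derive(categories, _CATEGORY_TO_APPROACH2)


def methodology_concordance(categories: Mapping[str, str]) -> dict[str, int]:
    """How many interactors the two selection criteria agree on, by label."""
    concordant_wt = sum(1 for c in categories.values() if c == "wt_in_both")
    concordant_exp = sum(1 for c in categories.values() if c == "expanded_in_both")
    return {
        "n_total": len(categories),
        "n_concordant": concordant_wt + concordant_exp,
        "n_concordant_wt": concordant_wt,
        "n_concordant_expanded": concordant_exp,
    }


def _data_path(name: str):
    return resources.files("polyqppi.data").joinpath(name)


def load_methodology_table(path: str | Path | None = None) -> pd.DataFrame:
    """Per-interactor methodology category table (columns: gene_symbol,
    uniprot, category), indexed by UniProt accession."""
    source = path if path is not None else _data_path("interactor_methodology_categories.tsv")
    frame = pd.read_csv(source, sep="\t", dtype=str)
    return frame.set_index("uniprot", drop=False)


def load_validation_table(path: str | Path | None = None) -> pd.DataFrame:
    """Predicted (approach 2) vs experimentally determined preferences for
    the 71 ATXN1 partners, indexed by UniProt accession."""
    source = path if path is not None else _data_path("predictions_vs_suter2013.tsv")
    frame = pd.read_csv(source, sep="\t", dtype={"discordant": int}).astype(
        {"gene_symbol": str, "uniprot": str}
    )
    return frame.set_index("uniprot", drop=False)


@dataclass
class ComparisonResult:
    """Everything the end-to-end preference comparison produces."""

    records: list[PreferenceRecord]
    metrics: pd.DataFrame                       # one row per (interactor, variant)
    interface_sets: dict[str, dict[str, set[int]]]  # variant -> interactor -> receptor residues
    agreement: AgreementSummary | None
    skipped: list[str] = field(default_factory=list)

    def predicted_labels(self) -> dict[str, str]:
        return {rec.interactor_id: rec.predicted for rec in self.records}

    def records_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "interactor_id": r.interactor_id,
                    "metric_name": r.metric_name,
                    "value_wt": r.value_wt,
                    "value_exp": r.value_exp,
                    "predicted": r.predicted,
                    "experimental": r.experimental,
                }
                for r in self.records
            ]
        )


def _records_from_frame(metadata: pd.DataFrame, base_dir: Path | None) -> dict[str, dict[str, list[DockRecord]]]:
    required = {"interactor_id", "variant", "model_id", "structure_path"}
    missing = required - set(metadata.columns)
    if missing:
        raise ValueError(f"dock metadata lacks columns {sorted(missing)}")
    score_cols = [
        c for c in metadata.columns if c not in required and pd.api.types.is_numeric_dtype(metadata[c])
    ]
    grouped: dict[str, dict[str, list[DockRecord]]] = {}
    for row in metadata.itertuples(index=False):
        path = Path(row.structure_path)
        if base_dir is not None and not path.is_absolute():
            path = base_dir / path
        rec = DockRecord(
            interactor_id=str(row.interactor_id),
            variant=str(row.variant),
            model_id=str(row.model_id),
            scores={c: float(getattr(row, c)) for c in score_cols},
            structure_path=str(path),
        )
        grouped.setdefault(rec.interactor_id, {}).setdefault(rec.variant, []).append(rec)
    return grouped


def run_full_comparison(
    metadata: pd.DataFrame,
    metric_name: str = DEFAULT_METRIC,
    criterion: str = "lowest_zscore",
    probability_field: str = "probability",
    receptor_chain: str = "A",
    partner_chain: str = "B",
    experimental: Mapping[str, str] | None = None,
    threshold: float = 0.01,
    n_points: int = 960,
    base_dir: str | Path | None = None,
) -> ComparisonResult:
    """End-to-end comparison: select models, measure interfaces, classify.

    ``metadata`` has one row per docking model (columns interactor_id,
    variant, model_id, structure_path plus numeric score columns, at least
    ``zscore`` and the probability field).  Interactors missing one of the
    two variants are skipped with a logged warning.  Deterministic for
    fixed inputs.
    """
    if metric_name not in METRIC_NAMES:
        raise ValueError(f"unknown metric {metric_name!r}; choose from {METRIC_NAMES}")
    logger.info("classifying on metric %s with criterion %s", metric_name, criterion)
    grouped = _records_from_frame(metadata, Path(base_dir) if base_dir else None)
    tolerance = _METRIC_TOLERANCE[metric_name]

    records: list[PreferenceRecord] = []
    metric_rows: list[dict] = []
    interface_sets: dict[str, dict[str, set[int]]] = {v: {} for v in VARIANTS}
    skipped: list[str] = []

    for interactor_id in sorted(grouped):
        by_variant = grouped[interactor_id]
        if any(v not in by_variant for v in VARIANTS):
            logger.warning("interactor %s lacks a dock for one variant; skipped", interactor_id)
            skipped.append(interactor_id)
            continue
        values: dict[str, float] = {}
        for variant in VARIANTS:
            best = select_docking_model(by_variant[variant], criterion, probability_field)
            structure = assign_vdw_radii(read_pdb(best.structure_path))
            report = residue_delta_asa(
                structure,
                receptor_chain,
                partner_chain,
                threshold=threshold,
                n_points=n_points,
            )
            metrics = report.metrics()
            values[variant] = metrics[metric_name]
            interface_sets[variant][interactor_id] = report.interface_residue_numbers(
                receptor_chain
            )
            metric_rows.append(
                {
                    "interactor_id": interactor_id,
                    "variant": variant,
                    "model_id": best.model_id,
                    **metrics,
                    "n_hbonds": len(report.hbonds),
                    "n_salt_bridges": len(report.salt_bridges),
                }
            )
        predicted = classify_preference(
            values["wt_Q29"], values["expanded_Q82"], tolerance
        )
        records.append(
            PreferenceRecord(
                interactor_id=interactor_id,
                metric_name=metric_name,
                value_wt=values["wt_Q29"],
                value_exp=values["expanded_Q82"],
                predicted=predicted,
                experimental=(experimental or {}).get(interactor_id, "unknown"),
            )
        )

    agreement = None
    if experimental is not None:
        known = {r.interactor_id: r.experimental for r in records if r.experimental != "unknown"}
        if known:
            agreement = score_agreement(
                {k: next(r.predicted for r in records if r.interactor_id == k) for k in known},
                known,
            )
    return ComparisonResult(
        records=records,
        metrics=pd.DataFrame(metric_rows),
        interface_sets=interface_sets,
        agreement=agreement,
        skipped=skipped,
    )
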