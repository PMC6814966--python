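"""ATXN1 sequence-region schemes and region-resolved interface tallies.

Wild-type ATXN1 (Q29) is 816 residues with the polyQ tract at 197–225 and
the AXH domain at 562–693.  The disease-length Q82 variant inserts 53 extra
glutamines inside the tract, so every coordinate downstream of residue 196
shifts by +53 and the protein is 869 residues long.  Interface residues are
tallied in six regions: before/after the polyQ (these two, together with the
tract itself, partition the sequence), the two 20-residue flanks, and the
AXH domain (flanks and AXH overlap the partition regions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import stats as vstats

__all__ = [
    "RegionScheme",
    "RegionTally",
    "PARTITION_LABELS",
    "REGION_LABELS",
    "build_scheme",
    "assign_regions",
    "tally_regions",
    "region_counts_per_complex",
    "compare_region_tallies",
]

#: The three labels that partition the full sequence.
PARTITION_LABELS = ("before_polyQ", "polyQ", "after_polyQ")
#: All six standard region labels, in reporting order.
REGION_LABELS = (
    "before_polyQ",
    "polyQ",
    "after_polyQ",
    "flank_before_20",
    "flank_after_20",
    "AXH",
)

_WT_LENGTH = 816
_POLYQ_START = 197
_WT_POLYQ_LEN = 29
_EXP_POLYQ_LEN = 82
_OFFSET = _EXP_POLYQ_LEN - _WT_POLYQ_LEN  # +53 for every residue after 196

# wt coordinates of regions lying entirely downstream of the polyQ.
_WT_AXH = (562, 693)
_EXTRA_WT_REGIONS = {  # optional labels; no headline result depends on them
    "SAR": (494, 604),
    "RNA_binding": (540, 766),
    "NLS": (794, 797),
    "C_terminal": (690, 816),
}


@dataclass(frozen=True)
class RegionScheme:
    variant: str                 # "wt_Q29" or "expanded_Q82"
    length: int
    regions: tuple[tuple[str, int, int], ...]  # (label, start, end), 1-based inclusive

    def bounds(self, label: str) -> tuple[int, int]:
        for lab, start, end in self.regions:
            if lab == label:
                return (start, end)
        raise KeyError(f"region {label!r} not in scheme {self.variant}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _, _ in self.regions)


def build_scheme(variant: str, include_extras: bool = False) -> RegionScheme:
    """Region scheme for one ATXN1 variant.

    ``wt_Q29``: 816 residues, polyQ 197–225, AXH 562–693.
    ``expanded_Q82``: polyQ 197–278; all downstream bounds +53; length 869.
    """
    if variant == "wt_Q29":
        offset, polyq_len = 0, _WT_POLYQ_LEN
    elif variant == "expanded_Q82":
        offset, polyq_len = _OFFSET, _EXP_POLYQ_LEN
    else:
        raise ValueError(f"unknown variant {variant!r} (expected wt_Q29 or expanded_Q82)")

    polyq_end = _POLYQ_START + polyq_len - 1
    length = _WT_LENGTH + offset
    regions = [
        ("before_polyQ", 1, _POLYQ_START - 1),
        ("polyQ", _POLYQ_START, polyq_end),
        ("after_polyQ", polyq_end + 1, length),
        ("flank_before_20", _POLYQ_START - 20, _POLYQ_START - 1),
        ("flank_after_20", polyq_end + 1, polyq_end + 20),
        ("AXH", _WT_AXH[0] + offset, _WT_AXH[1] + offset),
    ]
    if include_extras:
        for label, (start, end) in _EXTRA_WT_REGIONS.items():
            regions.append((label, start + offset, end + offset))
    return RegionScheme(variant=variant, length=length, regions=tuple(regions))


def assign_regions(residue_number: int, scheme: RegionScheme) -> set[str]:
    """Every region label whose interval contains the residue."""
    if not 1 <= residue_number <= scheme.length:
        raise ValueError(
            f"residue {residue_number} outside scheme {scheme.variant} (length {scheme.length})"
        )
    return {
        label
        for label, start, end in scheme.regions
        if start <= residue_number <= end
    }


@dataclass
class RegionTally:
    """Interface-residue counts per region, pooled over a set of complexes."""

    counts: dict[str, int]
    percentages: dict[str, float]     # over the three-way partition
    n_complexes: int
    profile: np.ndarray = field(repr=False)  # per-position interface frequency
    scheme: RegionScheme = field(repr=False, default=None)


def _count_one(residue_numbers: Iterable[int], scheme: RegionScheme) -> dict[str, int]:
    counts = {label: 0 for label in scheme.labels}
    for num in residue_numbers:
        for label in assign_regions(num, scheme):
            counts[label] += 1
    return counts


def tally_regions(
    interface_sets: Sequence[Iterable[int]],
    scheme: RegionScheme,
    unique_positions: bool = False,
) -> RegionTally:
    """Pool interface residues over complexes and tally them per region.

    By default a position contributes once per complex it appears in
    (multiplicity pooling); with ``unique_positions`` each position counts
    at most once overall.  Percentages are reported on the three-way
    partition {before_polyQ, polyQ, after_polyQ} so they sum to 100.
    Also computes the per-position frequency profile (fraction of
    complexes with that residue at the interface).
    """
    if len(interface_sets) == 0:
        raise ValueError("tally_regions requires at least one complex (percentages undefined)")

    profile = np.zeros(scheme.length)
    for residues in interface_sets:
        for num in set(residues):
            if not 1 <= num <= scheme.length:
                raise ValueError(
                    f"residue {num} outside scheme {scheme.variant} (length {scheme.length})"
                )
            profile[num - 1] += 1
    profile /= len(interface_sets)

    if unique_positions:
        pooled = set().union(*(set(s) for s in interface_sets))
        counts = _count_one(pooled, scheme)
    else:
        counts = {label: 0 for label in scheme.labels}
        for residues in interface_sets:
            for label, c in _count_one(set(residues), scheme).items():
                counts[label] += c

    denom = sum(counts[label] for label in PARTITION_LABELS)
    percentages = {
        label: (100.0 * counts[label] / denom if denom else 0.0)
        for label in scheme.labels
    }
    return RegionTally(
        counts=counts,
        percentages=percentages,
        n_complexes=len(interface_sets),
        profile=profile,
        scheme=scheme,
    )


def region_counts_per_complex(
    interface_sets: Sequence[Iterable[int]],
    scheme: RegionScheme,
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """One row per complex, one column per region label."""
    rows = [_count_one(set(s), scheme) for s in interface_sets]
    frame = pd.DataFrame(rows)
    return frame[list(labels or scheme.labels)]


def compare_region_tallies(
    counts_wt: pd.DataFrame,
    counts_exp: pd.DataFrame,
) -> pd.DataFrame:
    """Paired per-region comparison of wt vs expanded interface counts.

    Both frames must be indexed by the same ordered interactors (rows) with
    region labels as columns.  For each region: the per-interactor
    (expanded − wt) differences, the exact two-sided sign test on them, and
    the pooled percentage difference (the region profile of the
    wt-vs-expanded figure comparisons).
    """
    if list(counts_wt.index) != list(counts_exp.index):
        raise ValueError("mismatched interactor sets between wt and expanded tallies")
    if list(counts_wt.columns) != list(counts_exp.columns):
        raise ValueError("mismatched region labels between wt and expanded tallies")

    rows = []
    for label in counts_wt.columns:
        diffs = (counts_exp[label] - counts_wt[label]).to_numpy()
        n_pos, n_neg, n_tie, p = vstats.sign_test_from_differences(diffs)
        total_wt = int(counts_wt[label].sum())
        total_exp = int(counts_exp[label].sum())
        denom = max(total_wt, 1)
        rows.append(
            {
                "region": label,
                "total_wt": total_wt,
                "total_exp": total_exp,
                "mean_diff": float(np.mean(diffs)),
                "pct_diff": 100.0 * (total_exp - total_wt) / denom,
                "n_pos": n_pos,
                "n_neg": n_neg,
                "n_tie": n_tie,
                "sign_test_p": p,
            }
        )
    return pd.DataFrame(rows).set_index("region")
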