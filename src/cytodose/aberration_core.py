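"""Domain types and scoring rules for telomere/centromere-stained metaphases.

Unstable chromosomal aberrations scored after telomere (TTAGGG) and
centromere PNA staining carry enough signal information to reconstruct the
number of unrepaired or mis-repaired DNA double-strand breaks (DSB) behind
each aberration class:

* dicentric chromosomes and centric rings, each normally accompanied by an
  acentric fragment carrying four telomere signals, count as two DSB;
* excess four-telomere fragments (beyond one per dicentric/ring) are fusion
  products without a visible dicentric and also count as two DSB;
* acentric fragments with two telomere signals are terminal deletions
  (one DSB); fragments with no telomere signal are interstitial deletions
  (two DSB); loss of both telomere signals on one arm is a telomere
  deletion (one DSB);
* acentric rings require two breaks and default to two DSB (configurable).

Only complete metaphases — exactly 46 centromeres — enter any tally, so
that missing chromosomes cannot masquerade as deletions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "MetaphaseRecord",
    "AberrationTally",
    "DsbBreakdown",
    "filter_analyzable",
    "tally",
    "combine_tallies",
    "count_dsb",
    "f_ratio",
    "read_score_table",
    "write_score_table",
    "read_tally_table",
    "write_tally_table",
    "tallies_to_frame",
    "dsb_breakdown_to_json",
]

ANALYZABLE_CENTROMERE_COUNT = 46

#: CSV short column name -> dataclass attribute, shared by both dialects.
COUNT_COLUMNS = {
    "dic": "n_dicentric",
    "cring": "n_centric_ring",
    "aring": "n_acentric_ring",
    "ace_4tel": "n_ace_4tel",
    "ace_2tel": "n_ace_2tel",
    "ace_0tel": "n_ace_0tel",
    "teldel": "n_tel_deletion",
}

PER_CELL_HEADER = ["donor_id", "group_id", "dose_gy", "centromere_count", *COUNT_COLUMNS]
AGGREGATED_HEADER = ["group_id", "dose_gy", "n_cells", *COUNT_COLUMNS]


def _check_count(name: str, value: int) -> int:
    if not isinstance(value, (int,)) or isinstance(value, bool):
        try:
            as_int = int(value)
        except (TypeError, ValueError):
            raise TypeError(f"{name} must be an integer, got {value!r}") from None
        if as_int != value:
            raise ValueError(f"{name} must be an integer, got {value!r}")
        value = as_int
    if value < 0:
        raise ValueError(f"{name} must be >= 0, got {value}")
    return value


@dataclass(frozen=True)
class MetaphaseRecord:
    """One scored metaphase cell.

    ``n_ace_4tel`` is the count of acentric fragments with four telomere
    signals (fusion by-products, "ace(+/+)"); ``n_ace_2tel`` terminal
    deletions ("ace(+/-)"); ``n_ace_0tel`` interstitial deletions
    ("ace(-/-)"); ``n_tel_deletion`` loss of both telomere signals on one
    chromosome arm.
    """

    donor_id: str
    group_id: str
    dose_gy: float
    centromere_count: int
    n_dicentric: int = 0
    n_centric_ring: int = 0
    n_acentric_ring: int = 0
    n_ace_4tel: int = 0
    n_ace_2tel: int = 0
    n_ace_0tel: int = 0
    n_tel_deletion: int = 0

    def __post_init__(self) -> None:
        if self.dose_gy < 0:
            raise ValueError(f"dose_gy must be >= 0, got {self.dose_gy}")
        object.__setattr__(
            self, "centromere_count", _check_count("centromere_count", self.centromere_count)
        )
        for attr in COUNT_COLUMNS.values():
            object.__setattr__(self, attr, _check_count(attr, getattr(self, attr)))

    @property
    def is_analyzable(self) -> bool:
        """A metaphase enters analysis only when all 46 centromeres are present."""
        return self.centromere_count == ANALYZABLE_CENTROMERE_COUNT


@dataclass(frozen=True)
class AberrationTally:
    """Aggregate aberration counts for one (group, dose) cell population."""

    group_id: str
    dose_gy: float
    n_cells: int
    n_dicentric: int = 0
    n_centric_ring: int = 0
    n_acentric_ring: int = 0
    n_ace_4tel: int = 0
    n_ace_2tel: int = 0
    n_ace_0tel: int = 0
    n_tel_deletion: int = 0

    def __post_init__(self) -> None:
        if self.dose_gy < 0:
            raise ValueError(f"dose_gy must be >= 0, got {self.dose_gy}")
        object.__setattr__(self, "n_cells", _check_count("n_cells", self.n_cells))
        for attr in COUNT_COLUMNS.values():
            object.__setattr__(self, attr, _check_count(attr, getattr(self, attr)))


@dataclass(frozen=True)
class DsbBreakdown:
    """Per-class contributions to the reconstructed DSB count of a tally."""

    dsb_from_dic_and_rings: int
    dsb_from_acentric_rings: int
    dsb_from_terminal_deletions: int
    dsb_from_interstitial_deletions: int
    dsb_from_tel_deletions: int
    dsb_from_excess_4tel_fragments: int

    @property
    def total_dsb(self) -> int:
        return (
            self.dsb_from_dic_and_rings
            + self.dsb_from_acentric_rings
            + self.dsb_from_terminal_deletions
            + self.dsb_from_interstitial_deletions
            + self.dsb_from_tel_deletions
            + self.dsb_from_excess_4tel_fragments
        )


def filter_analyzable(records: Iterable[MetaphaseRecord]) -> list[MetaphaseRecord]:
    """Keep only complete metaphases (46 centromeres), preserving order."""
    return [r for r in records if r.is_analyzable]


def tally(
    records: Sequence[MetaphaseRecord],
    group_id: str | None = None,
    dose_gy: float | None = None,
) -> AberrationTally:
    """Aggregate analyzable records from one (group, dose) into a tally.

    ``group_id``/``dose_gy`` default to the (unique) values found in the
    records; a mix of groups or doses is rejected, naming the offending
    record, because a tally is the unit that enters curve fitting.
    """
    records = list(records)
    if not records:
        raise ValueError("cannot tally an empty record list (no cells)")
    first = records[0]
    group_id = first.group_id if group_id is None else group_id
    dose_gy = first.dose_gy if dose_gy is None else dose_gy
    sums = dict.fromkeys(COUNT_COLUMNS.values(), 0)
    for i, rec in enumerate(records):
        if not rec.is_analyzable:
            raise ValueError(
                f"record {i} (donor {rec.donor_id!r}) has {rec.centromere_count} "
                "centromeres; only 46-centromere metaphases may be tallied"
            )
        if rec.group_id != group_id:
            raise ValueError(
                f"record {i} (donor {rec.donor_id!r}) belongs to group "
                f"{rec.group_id!r}, expected {group_id!r}"
            )
        if rec.dose_gy != dose_gy:
            raise ValueError(
                f"record {i} (donor {rec.donor_id!r}) was scored at "
                f"{rec.dose_gy} Gy, expected {dose_gy} Gy"
            )
        for attr in sums:
            sums[attr] += getattr(rec, attr)
    return AberrationTally(group_id=group_id, dose_gy=dose_gy, n_cells=len(records), **sums)


def combine_tallies(tallies: Sequence[AberrationTally]) -> AberrationTally:
    """Sum tallies from the same (group, dose); counts and cells add."""
    if not tallies:
        raise ValueError("cannot combine an empty tally list")
    first = tallies[0]
    for t in tallies[1:]:
        if t.group_id != first.group_id or t.dose_gy != first.dose_gy:
            raise ValueError("tallies to combine must share group_id and dose_gy")
    sums = {
        attr: sum(getattr(t, attr) for t in tallies) for attr in COUNT_COLUMNS.values()
    }
    return AberrationTally(
        group_id=first.group_id,
        dose_gy=first.dose_gy,
        n_cells=sum(t.n_cells for t in tallies),
        **sums,
    )


def count_dsb(tally: AberrationTally, acentric_ring_dsb_weight: int = 2) -> DsbBreakdown:
    """Reconstruct the DSB count of a tally from fixed per-class weights.

    Dicentrics and centric rings (with their accompanying four-telomere
    fragment) are two DSB each; a four-telomere fragment in excess of the
    dicentric+ring count is itself a fusion product and scores two DSB;
    terminal deletions one, interstitial deletions two, telomere deletions
    one. Acentric rings need two breaks to form, hence the default weight
    of 2; the weight is configurable because no scoring convention fixes it.
    """
    fusion_events = tally.n_dicentric + tally.n_centric_ring
    excess_4tel = max(0, tally.n_ace_4tel - fusion_events)
    return DsbBreakdown(
        dsb_from_dic_and_rings=2 * fusion_events,
        dsb_from_acentric_rings=acentric_ring_dsb_weight * tally.n_acentric_ring,
        dsb_from_terminal_deletions=tally.n_ace_2tel,
        dsb_from_interstitial_deletions=2 * tally.n_ace_0tel,
        dsb_from_tel_deletions=tally.n_tel_deletion,
        dsb_from_excess_4tel_fragments=2 * excess_4tel,
    )


def f_ratio(tally: AberrationTally) -> float:
    """Centric rings per dicentric — the F-ratio consistency check.

    Healthy European donors typically show about 0.05 rings per dicentric.
    (The ratio is sometimes loosely described in the inverse direction in
    the literature; this function always returns rings/dicentrics.)
    """
    if tally.n_dicentric == 0:
        raise ZeroDivisionError(
            "F-ratio is undefined when no dicentrics were scored"
        )
    return tally.n_centric_ring / tally.n_dicentric


# ---------------------------------------------------------------------------
# File contracts: two CSV dialects (per-metaphase and pre-aggregated)
# ---------------------------------------------------------------------------


def _attr_frame_to_records(df: pd.DataFrame) -> list[MetaphaseRecord]:
    records = []
    for row in df.itertuples(index=False):
        records.append(
            MetaphaseRecord(
                donor_id=str(row.donor_id),
                group_id=str(row.group_id),
                dose_gy=float(row.dose_gy),
                centromere_count=int(row.centromere_count),
                **{attr: int(getattr(row, col)) for col, attr in COUNT_COLUMNS.items()},
            )
        )
    return records


def read_score_table(path: str | Path) -> list[MetaphaseRecord] | list[AberrationTally]:
    """Read a score table in either accepted dialect.

    Per-metaphase rows (header starting ``donor_id,group_id,...``) give
    MetaphaseRecord objects; pre-aggregated rows (header starting
    ``group_id,dose_gy,n_cells,...``) give AberrationTally objects. The
    separator (comma or tab) is sniffed.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    cols = list(df.columns)
    if cols == PER_CELL_HEADER:
        return _attr_frame_to_records(df)
    if cols == AGGREGATED_HEADER:
        return [
            AberrationTally(
                group_id=str(row.group_id),
                dose_gy=float(row.dose_gy),
                n_cells=int(row.n_cells),
                **{attr: int(getattr(row, col)) for col, attr in COUNT_COLUMNS.items()},
            )
            for row in df.itertuples(index=False)
        ]
    raise ValueError(
        f"malformed CSV header in {path}: got {cols}; expected the "
        f"per-metaphase dialect {PER_CELL_HEADER} or the aggregated "
        f"dialect {AGGREGATED_HEADER}"
    )


def write_score_table(records: Sequence[MetaphaseRecord], path: str | Path) -> None:
    """Write per-metaphase records in the canonical CSV dialect."""
    rows = [
        {
            "donor_id": r.donor_id,
            "group_id": r.group_id,
            "dose_gy": r.dose_gy,
            "centromere_count": r.centromere_count,
            **{col: getattr(r, attr) for col, attr in COUNT_COLUMNS.items()},
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=PER_CELL_HEADER).to_csv(path, index=False)


def tallies_to_frame(tallies: Sequence[AberrationTally]) -> pd.DataFrame:
    rows = [
        {
            "group_id": t.group_id,
            "dose_gy": t.dose_gy,
            "n_cells": t.n_cells,
            **{col: getattr(t, attr) for col, attr in COUNT_COLUMNS.items()},
        }
        for t in tallies
    ]
    return pd.DataFrame(rows, columns=AGGREGATED_HEADER)


def write_tally_table(tallies: Sequence[AberrationTally], path: str | Path) -> None:
    tallies_to_frame(tallies).to_csv(path, index=False)


def read_tally_table(path: str | Path) -> list[AberrationTally]:
    out = read_score_table(path)
    if out and isinstance(out[0], MetaphaseRecord):
        raise ValueError(f"{path} holds per-metaphase rows, not aggregated tallies")
    return out  # type: ignore[return-value]


def dsb_breakdown_to_json(breakdown: DsbBreakdown) -> str:
    payload = dataclasses.asdict(breakdown)
    payload["total_dsb"] = breakdown.total_dsb
    return json.dumps(payload, indent=2)
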