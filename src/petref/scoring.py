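"""Reference-region selection: the median < -0.5 rule and structure grouping.

A candidate reference is scored by the median, over all target regions, of
the Pearson correlation between target SUVr and age. Candidates whose
median is strictly below the threshold (default -0.5) are selected and
pooled into anatomical structures (cerebellum lobules + vermis ->
"cerebellum", "Pons" -> "pons"), which is how the result "the cerebellum
and the pons are the only age-stable references" is expressed.

The published 120-region coefficient table for the conventional- and
digital-camera control databases ships as a packaged TSV fixture and is
the worked-example surface for the selection rule.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .atlas import infer_structure
from .grid import NormalizationSummary

#: sha256 of the packaged coefficient table (guards accidental edits).
_FIXTURE_SHA256 = "2fe84822fc11cdb8ba6698861197f359c0a2c174674d0c33cee3101255af6f02"
_FIXTURE_NAME = "table1_correlations.tsv"

_SYSTEMS = ("conventional", "digital")


def parse_printed_coefficient(text: str) -> float:
    """Parse a printed correlation coefficient, normalizing typography.

    Accepts typographic minus signs (U+2212), thin spaces and ordinary
    whitespace between sign and digits: ``"− 0.51"`` -> ``-0.51``.
    """
    cleaned = re.sub(r"[\s  ]+", "", text.replace("−", "-"))
    return float(cleaned)


def load_table1_fixture() -> pd.DataFrame:
    """The published per-reference coefficient table (120 rows).

    Columns: ``strongest_conventional``, ``median_conventional``,
    ``strongest_digital``, ``median_digital``; index: region name at full
    printed precision. Raises if the packaged file fails its checksum.
    """
    raw = resources.files("petref").joinpath("data", _FIXTURE_NAME).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise ValueError(
            f"packaged coefficient table checksum mismatch: {digest} != {_FIXTURE_SHA256}"
        )
    from io import BytesIO

    df = pd.read_csv(BytesIO(raw), sep="\t", index_col="region")
    if len(df) != 120:
        raise ValueError(f"expected 120 fixture rows, found {len(df)}")
    return df


def fixture_summary(system: str) -> NormalizationSummary:
    """The fixture's per-reference scores as a NormalizationSummary."""
    if system not in _SYSTEMS:
        raise ValueError(f"system must be one of {_SYSTEMS}")
    df = load_table1_fixture()
    return NormalizationSummary(
        region_names=[str(i) for i in df.index],
        median_r=df[f"median_{system}"].to_numpy(dtype=float),
        strongest_r=df[f"strongest_{system}"].to_numpy(dtype=float),
        system_label=system,
    )


@dataclass
class SelectionResult:
    """Outcome of the median-threshold selection rule."""

    threshold: float
    selected_regions: list[str]  # ordered by ascending median
    selected_structures: list[str]  # deduplicated, first-appearance order
    ranking: list[str]  # all references, ascending median, name tie-break

    def __post_init__(self) -> None:
        if set(self.selected_regions) - set(self.ranking):
            raise ValueError("selected regions must appear in the ranking")


def rank_references(summary: NormalizationSummary) -> list[str]:
    """References ordered by ascending median coefficient (best first).

    Ties resolve lexicographically by region name, so the order is total
    and stable across runs.
    """
    if not summary.region_names:
        raise ValueError("summary is empty")
    order = sorted(
        range(len(summary.region_names)),
        key=lambda i: (summary.median_r[i], summary.region_names[i]),
    )
    return [summary.region_names[i] for i in order]


def select_references(
    summary: NormalizationSummary,
    threshold: float = -0.5,
    structure_fn=infer_structure,
) -> SelectionResult:
    """Apply the strict median < threshold rule and group into structures.

    A region whose median equals the threshold exactly is *not* selected.
    An empty selection is a valid outcome.
    """
    ranking = rank_references(summary)
    medians = dict(zip(summary.region_names, summary.median_r))
    selected = [r for r in ranking if medians[r] < threshold]
    structures: list[str] = []
    for region in selected:
        s = structure_fn(region)
        if s not in structures:
            structures.append(s)
    return SelectionResult(
        threshold=float(threshold),
        selected_regions=selected,
        selected_structures=structures,
        ranking=ranking,
    )


def group_selected_structures(selection: SelectionResult, structure_fn=infer_structure) -> list[str]:
    """Deduplicated structures of the selected regions, ranking order."""
    structures: list[str] = []
    for region in selection.selected_regions:
        s = structure_fn(region)
        if s not in structures:
            structures.append(s)
    return structures
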