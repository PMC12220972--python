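"""End-to-end pipeline: calls -> paired clonotypes -> networks -> labels."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .resolve import resolve_and_pair, pairing_rate
from .network import build_networks, concat_labels, metrics_table, ClonalNetwork


@dataclass
class PipelineResult:
    pairs: pd.DataFrame
    drops: pd.DataFrame
    networks: dict[tuple[str, str], ClonalNetwork]
    labels: pd.DataFrame
    metrics: pd.DataFrame
    pairing_rate_pct: float


def run_pipeline(cells: pd.DataFrame, calls: pd.DataFrame) -> PipelineResult:
    """Resolve chain calls, build identity networks, and label every cell.

    ``cells`` is the per-cell metadata table (cell_id, patient_id,
    compartment, timepoint, lineage, phenotype); ``calls`` the
    chain-level clonotype call table.  Cells without a paired TCR are
    reported in ``drops`` and absent from the label table.
    """
    pairs, drops = resolve_and_pair(calls, all_cell_ids=cells["cell_id"])
    networks = build_networks(pairs, cells)
    labels = concat_labels(networks)
    metrics = metrics_table(networks)
    return PipelineResult(
        pairs=pairs,
        drops=drops,
        networks=networks,
        labels=labels,
        metrics=metrics,
        pairing_rate_pct=pairing_rate(len(pairs), len(cells)),
    )
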