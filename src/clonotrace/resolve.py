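"""Resolve chain-level clonotype calls into one paired TCRab per cell.

For each barcode and locus the most abundant clonotype wins; ties on
read count are broken by the highest alignment score, and any remaining
ties lexicographically by junction sequence so resolution is fully
deterministic.  Only cells with both a resolved TRA and TRB are kept.
"""

from __future__ import annotations

import pandas as pd

REQUIRED_COLUMNS = ("cell_id", "locus", "junction_aa", "duplicate_count", "score")
LOCI = ("TRA", "TRB")


def _validate_calls(calls: pd.DataFrame) -> None:
    missing = set(REQUIRED_COLUMNS) - set(calls.columns)
    if missing:
        raise ValueError(f"call table missing columns: {sorted(missing)}")
    bad = set(calls["locus"].unique()) - set(LOCI)
    if bad:
        raise ValueError(f"unknown loci in call table: {sorted(bad)}")


def resolve_chain(calls: pd.DataFrame) -> str | None:
    """Winning junction for one cell and one locus (None if no calls)."""
    if len(calls) == 0:
        return None
    ordered = calls.sort_values(
        ["duplicate_count", "score", "junction_aa"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    return str(ordered["junction_aa"].iloc[0])


def resolve_chains(calls: pd.DataFrame) -> pd.DataFrame:
    """Resolve every (cell, locus) group at once; one winning row each."""
    _validate_calls(calls)
    ordered = calls.sort_values(
        ["cell_id", "locus", "duplicate_count", "score", "junction_aa"],
        ascending=[True, True, False, False, True],
        kind="mergesort",
    )
    return ordered.drop_duplicates(["cell_id", "locus"], keep="first").reset_index(drop=True)


def pair_cells(resolved: pd.DataFrame, all_cell_ids=None
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep cells with both chains; report dropped cells with a reason.

    Returns (pairs, drops): pairs has columns cell_id, cdr3a, cdr3b;
    drops has cell_id and reason in {missing_TRA, missing_TRB, no_tcr}
    (no_tcr only reportable when ``all_cell_ids`` supplies the full cell
    universe).
    """
    wide = (
        resolved.pivot_table(index="cell_id", columns="locus", values="junction_aa",
                             aggfunc="first")
        .reindex(columns=list(LOCI))
    )
    has_a = wide["TRA"].notna()
    has_b = wide["TRB"].notna()
    pairs = (
        wide[has_a & has_b]
        .rename(columns={"TRA": "cdr3a", "TRB": "cdr3b"})
        .reset_index()[["cell_id", "cdr3a", "cdr3b"]]
    )
    pairs.columns.name = None

    drops = []
    drops.append(pd.DataFrame({"cell_id": wide.index[has_a & ~has_b], "reason": "missing_TRB"}))
    drops.append(pd.DataFrame({"cell_id": wide.index[~has_a & has_b], "reason": "missing_TRA"}))
    if all_cell_ids is not None:
        absent = pd.Index(all_cell_ids).difference(wide.index)
        drops.append(pd.DataFrame({"cell_id": absent, "reason": "no_tcr"}))
    drop_df = pd.concat(drops, ignore_index=True)
    return pairs, drop_df


def resolve_and_pair(calls: pd.DataFrame, all_cell_ids=None
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    return pair_cells(resolve_chains(calls), all_cell_ids=all_cell_ids)


def pairing_rate(n_paired: int, n_rna_cells: int) -> float:
    """Percentage of RNA cells with a resolved TCRab pair, to 1 decimal."""
    if n_rna_cells <= 0:
        raise ValueError("n_rna_cells must be > 0")
    if n_paired < 0 or n_paired > n_rna_cells:
        raise ValueError("n_paired must be in [0, n_rna_cells]")
    return round(100.0 * n_paired / n_rna_cells, 1)
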