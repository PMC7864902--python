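"""Readers and writers shared by the command-line stages.

All tabular formats are tab-delimited UTF-8 with '.' decimals; nested
results are JSON. Every CLI run drops a provenance JSON (parameters plus
package version) beside its outputs so any file can be regenerated
byte-for-byte.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

import protract
from protract.enrichment import ContingencyTable, EnrichmentResult
from protract.polysome import FractionSignal, Trace, TraceSegmentation
from protract.ppt_scan import PPTProfile
from protract.quant import BlotTable, NormalizedRatio

PROFILE_COLUMNS = ["protein_id", "seq_length", "n_tracts", "longest_tract", "total_prolines"]


def write_profiles_tsv(profiles: Sequence[PPTProfile], path: str | Path) -> None:
    df = pd.DataFrame(
        [(p.protein_id, p.seq_length, p.n_tracts, p.longest_tract, p.total_prolines)
         for p in profiles],
        columns=PROFILE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_profiles_tsv(path: str | Path) -> list[PPTProfile]:
    df = pd.read_csv(path, sep="\t")
    missing = set(PROFILE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"profiles table {path} lacks columns: {sorted(missing)}")
    return [
        PPTProfile(
            protein_id=str(r.protein_id),
            seq_length=int(r.seq_length),
            n_tracts=int(r.n_tracts),
            longest_tract=int(r.longest_tract),
            total_prolines=int(r.total_prolines),
        )
        for r in df.itertuples()
    ]


def write_ranked_tsv(
    ranked: Sequence[tuple[int, PPTProfile]], path: str | Path
) -> None:
    df = pd.DataFrame(
        [(rank, p.protein_id, p.seq_length, p.n_tracts, p.longest_tract, p.total_prolines)
         for rank, p in ranked],
        columns=["rank"] + PROFILE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def parse_counts(text: str) -> ContingencyTable:
    """Parse ``"a,b,c,d"`` into a contingency table."""
    parts = [p.strip() for p in text.split(",")]
    if len(parts) != 4:
        raise ValueError(f"expected 4 comma-separated counts, got {len(parts)}")
    try:
        a, b, c, d = (int(p) for p in parts)
    except ValueError as exc:
        raise ValueError(f"counts must be integers: {text!r}") from exc
    return ContingencyTable(a, b, c, d)


def parse_fractions(set_frac: str, bg_frac: str) -> ContingencyTable:
    """Parse ``"k/n"`` carrier fractions for the set and the background."""
    def split(frac: str) -> tuple[int, int]:
        try:
            k, n = (int(p) for p in frac.split("/"))
        except ValueError as exc:
            raise ValueError(f"expected k/n integers, got {frac!r}") from exc
        if not 0 <= k <= n:
            raise ValueError(f"need 0 <= k <= n in {frac!r}")
        return k, n

    a, n_set = split(set_frac)
    c, n_bg = split(bg_frac)
    return ContingencyTable(a, n_set - a, c, n_bg - c)


def enrichment_to_json(result: EnrichmentResult) -> str:
    return json.dumps(result.to_dict(), indent=2) + "\n"


def read_blot_tables(
    path: str | Path, test_antibody: str, control_antibody: str
) -> dict[str, BlotTable]:
    """Read a tidy blot TSV (``blot_id lane antibody signal``), one table per blot."""
    df = pd.read_csv(path, sep="\t")
    required = {"blot_id", "lane", "antibody", "signal"}
    if not required.issubset(df.columns):
        raise ValueError(f"blot table needs columns {sorted(required)}")
    tables: dict[str, BlotTable] = {}
    for blot_id, sub in df.groupby("blot_id", sort=False):
        wide = sub.pivot_table(
            index="lane", columns="antibody", values="signal", sort=False
        )
        for ab in (test_antibody, control_antibody):
            if ab not in wide.columns or wide[ab].isna().any():
                raise ValueError(
                    f"blot {blot_id!r}: antibody {ab!r} missing for some lanes"
                )
        tables[str(blot_id)] = BlotTable(
            lanes=tuple(str(l) for l in wide.index),
            signals={
                test_antibody: tuple(wide[test_antibody]),
                control_antibody: tuple(wide[control_antibody]),
            },
            test_antibody=test_antibody,
            control_antibody=control_antibody,
        )
    return tables


def write_ratios_tsv(
    ratios_by_blot: dict[str, Sequence[NormalizedRatio]], path: str | Path
) -> None:
    rows = [
        (blot_id, r.lane, r.ratio)
        for blot_id, ratios in ratios_by_blot.items()
        for r in ratios
    ]
    pd.DataFrame(rows, columns=["blot_id", "lane", "ab_ratio"]).to_csv(
        path, sep="\t", index=False
    )


def read_ct_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "target_ct", "reference_ct"}
    if not required.issubset(df.columns):
        raise ValueError(f"CT table needs columns {sorted(required)}")
    return df


def read_trace_tsv(path: str | Path) -> Trace:
    """Two-column TSV ``position  absorbance``; a non-numeric first row is a header."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    try:
        float(df.iloc[0, 0])
    except (TypeError, ValueError):
        df = df.iloc[1:]
    if df.shape[1] < 2:
        raise ValueError(f"trace file {path} needs two columns")
    return Trace(
        positions=df.iloc[:, 0].astype(float).to_numpy(),
        absorbance=df.iloc[:, 1].astype(float).to_numpy(),
    )


def segmentation_to_json(seg: TraceSegmentation, trace: Trace) -> str:
    payload = {
        "regions": [
            {
                "label": r.label,
                "start_position": float(trace.positions[r.start_index]),
                "end_position": float(trace.positions[r.end_index]),
                "peak_position": float(trace.positions[r.peak_index]),
                "area": r.area,
            }
            for r in seg.regions
        ],
        "pm_ratio": seg.pm_ratio,
        "ratio_60_80": seg.ratio_60_80,
    }
    return json.dumps(payload, indent=2) + "\n"


def write_provenance(out_path: str | Path, subcommand: str, params: dict) -> None:
    """Record parameters and package version beside an output file."""
    out_path = Path(out_path)
    record = {
        "tool": "protract",
        "version": protract.__version__,
        "subcommand": subcommand,
        "parameters": {k: (str(v) if isinstance(v, Path) else v) for k, v in params.items()},
    }
    prov = out_path.with_name(out_path.name + ".provenance.json")
    prov.write_text(json.dumps(record, indent=2) + "\n")
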