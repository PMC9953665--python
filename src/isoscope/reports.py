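"""Fixed-format TSV/JSON report writing and the run manifest."""

from __future__ import annotations

import json
import os
from importlib import resources
from typing import Dict, List, Mapping

import pandas as pd

#: report name -> required column order
REPORT_SCHEMAS: Dict[str, List[str]] = {
    "consequences": ["variant_id", "transcript_id", "consequence", "protein_change"],
    "abundance": ["transcript_id", "est_count", "tpm", "gene_id", "pct_usage"],
    "alleles": [
        "variant_id",
        "transcript_id",
        "ref_reads",
        "alt_reads",
        "ambiguous_reads",
        "alt_fraction",
        "genotype",
    ],
    "phase": [
        "variant_a",
        "variant_b",
        "transcript_id",
        "ref_ref",
        "ref_alt",
        "alt_ref",
        "alt_alt",
        "verdict",
    ],
    "probes": [
        "fused_transcript_id",
        "junction_offset",
        "flank",
        "probe_sequence",
        "uniqueness",
        "n_hits",
    ],
    "junction_counts": ["fused_transcript_id", "sample", "junction_reads"],
    "conservation": ["ref_pos", "ref_char", "percent", "digit"],
    "contacts": [
        "chain_i",
        "residue_i",
        "resname_i",
        "chain_j",
        "residue_j",
        "resname_j",
        "min_distance",
        "kind",
        "structure_id",
    ],
}


class SchemaError(ValueError):
    """A table does not match its declared report schema."""


def write_report(name: str, table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a schema-checked TSV report (UTF-8, LF, fixed column order)."""
    if name not in REPORT_SCHEMAS:
        raise SchemaError(f"unknown report {name!r}")
    columns = REPORT_SCHEMAS[name]
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise SchemaError(f"report {name!r} missing columns {missing}")
    out = table.loc[:, columns]
    out.to_csv(path, sep="\t", index=False, lineterminator="\n", encoding="utf-8")


def read_report(name: str, path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != REPORT_SCHEMAS[name]:
        raise SchemaError(f"file {path} does not match schema for {name!r}")
    return df


def manifest_schema() -> dict:
    text = resources.files("isoscope.data").joinpath("manifest_schema.json").read_text()
    return json.loads(text)


def validate_manifest(manifest: Mapping) -> None:
    """Check the manifest against the bundled schema (required keys + types)."""
    schema = manifest_schema()
    types = {"string": str, "integer": int, "number": (int, float), "object": dict}
    for key, kind in schema["required"].items():
        if key not in manifest:
            raise SchemaError(f"manifest missing required key {key!r}")
        if not isinstance(manifest[key], types[kind]):
            raise SchemaError(f"manifest key {key!r} is not of type {kind}")


def write_manifest(manifest: Mapping, path: str | os.PathLike) -> None:
    validate_manifest(manifest)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
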