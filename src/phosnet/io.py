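"""Readers and writers for the pipeline's on-disk formats.

Formats handled here: SIF edge lists, STRING-style scored TSV, GMT gene
sets, and the two kinase--substrate prediction dialects (iGPS-like and
NetworKIN-like).  PSM tables and count matrices live in :mod:`phosnet.quant`.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InputFormatError

_SITE_ID = re.compile(r"^(?P<protein>[^:]+):(?P<residue>[STY])(?P<position>\d+)$")


def split_site_id(site_id: str) -> tuple[str, str, int]:
    """Split ``P00001:S263`` into (protein, residue, position)."""
    m = _SITE_ID.match(site_id)
    if not m:
        raise InputFormatError(f"bad site id {site_id!r}")
    return m.group("protein"), m.group("residue"), int(m.group("position"))


# ---------------------------------------------------------------------------
# kinase-substrate dialects
# ---------------------------------------------------------------------------

def write_igps_table(ksr: pd.DataFrame, path) -> None:
    """iGPS-like dialect: kinase, protein, position, residue (no scores)."""
    rows = []
    for r in ksr.itertuples(index=False):
        protein, residue, position = split_site_id(r.site_id)
        rows.append((r.kinase, protein, position, residue))
    pd.DataFrame(rows, columns=["kinase", "protein", "position", "residue"]).to_csv(
        path, sep="\t", index=False
    )


def parse_igps_table(path) -> pd.DataFrame:
    """Read the iGPS-like dialect into the common KSR frame.

    iGPS output is assumed pre-filtered upstream (10% FPR), so rows carry
    no score columns and always survive score filtering.
    """
    df = pd.read_csv(path, sep="\t", dtype={"kinase": str, "protein": str, "residue": str})
    required = {"kinase", "protein", "position", "residue"}
    missing = required - set(df.columns)
    if missing:
        raise InputFormatError(f"iGPS table missing column(s): {sorted(missing)}")
    return pd.DataFrame(
        {
            "kinase": df["kinase"],
            "site_id": df["protein"] + ":" + df["residue"] + df["position"].astype(str),
            "source": "igps",
            "networkin_score": np.nan,
            "netphorest_probability": np.nan,
        }
    )


def write_networkin_table(ksr: pd.DataFrame, path) -> None:
    """NetworKIN-like dialect: substrate, position, kinase, scores.

    The position token carries the residue letter (e.g. ``S263``) so the
    site is recoverable without a sequence database.
    """
    rows = []
    for r in ksr.itertuples(index=False):
        protein, residue, position = split_site_id(r.site_id)
        rows.append(
            (
                protein,
                f"{residue}{position}",
                r.kinase,
                r.networkin_score,
                r.netphorest_probability,
            )
        )
    pd.DataFrame(
        rows,
        columns=[
            "substrate",
            "position",
            "kinase",
            "networkin_score",
            "netphorest_probability",
        ],
    ).to_csv(path, sep="\t", index=False, float_format="%.4f")


def parse_networkin_table(path, id_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read the NetworKIN-like dialect into the common KSR frame.

    ``id_map`` optionally translates substrate accessions (e.g. a
    human-to-mouse ortholog mapping); identity by default.
    """
    df = pd.read_csv(path, sep="\t", dtype={"substrate": str, "position": str, "kinase": str})
    required = {"substrate", "position", "kinase", "networkin_score", "netphorest_probability"}
    missing = required - set(df.columns)
    if missing:
        raise InputFormatError(f"NetworKIN table missing column(s): {sorted(missing)}")
    substrate = df["substrate"].map(lambda s: (id_map or {}).get(s, s))
    return pd.DataFrame(
        {
            "kinase": df["kinase"],
            "site_id": substrate + ":" + df["position"],
            "source": "networkin",
            "networkin_score": df["networkin_score"].astype(float),
            "netphorest_probability": df["netphorest_probability"].astype(float),
        }
    )


def read_id_map(path) -> dict[str, str]:
    """Two-column TSV identifier mapping (from, to); no header."""
    df = pd.read_csv(path, sep="\t", header=None, names=["src", "dst"], dtype=str)
    return dict(zip(df["src"], df["dst"]))


# ---------------------------------------------------------------------------
# edge lists
# ---------------------------------------------------------------------------

def write_sif(edges: pd.DataFrame, path, interaction: str = "pp") -> None:
    out = pd.DataFrame(
        {
            "node_a": edges["node_a"],
            "interaction": interaction,
            "node_b": edges["node_b"],
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)


def read_sif(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 3:
        raise InputFormatError("SIF requires three tab-separated columns")
    return pd.DataFrame({"node_a": df[0], "node_b": df[2]})


def write_string_table(edges: pd.DataFrame, path) -> None:
    edges[["node_a", "node_b", "combined_score"]].to_csv(
        path, sep="\t", index=False, float_format="%.4f"
    )


def read_string_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"node_a": str, "node_b": str})
    required = {"node_a", "node_b", "combined_score"}
    missing = required - set(df.columns)
    if missing:
        raise InputFormatError(f"STRING table missing column(s): {sorted(missing)}")
    df["combined_score"] = df["combined_score"].astype(float)
    return df


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

def write_gmt(annotation: Mapping[str, tuple[str, list[str]]], path) -> None:
    lines = [
        "\t".join([term, desc, *genes])
        for term, (desc, genes) in annotation.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def parse_gmt(path) -> dict[str, tuple[str, list[str]]]:
    annotation: dict[str, tuple[str, list[str]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise InputFormatError(f"GMT line {lineno}: need term, description, genes")
        annotation[parts[0]] = (parts[1], parts[2:])
    return annotation
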