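"""Site-level spectral counting from localized phosphopeptide-spectrum matches.

A PSM (peptide-spectrum match) is one MS/MS spectrum assigned to a
phosphopeptide with its phospho-residues localized and a false localization
rate (FLR) estimate attached.  After FLR thresholding, spectra are tallied
per quantification unit -- the combination of protein accession, peptide
sequence and localized site set -- giving a semi-quantitative spectral-count
matrix across samples.  The unit deliberately keeps distinct peptides
covering the same residue as separate rows; a per-residue aggregation view
is available via :func:`collapse_to_sites`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import InputFormatError, ParameterError

_SITE_TOKEN = re.compile(r"^([STY])(\d+)$")

#: columns a PSM table must provide
PSM_COLUMNS = [
    "spectrum_id",
    "sample_id",
    "condition",
    "protein",
    "peptide",
    "site_list",
    "flr",
]


def parse_site_token(token: str) -> tuple[str, int]:
    """Parse a residue+position token like ``S263`` into ``("S", 263)``."""
    m = _SITE_TOKEN.match(token.strip())
    if not m:
        raise InputFormatError(f"unparsable site token: {token!r}")
    residue, pos = m.group(1), int(m.group(2))
    if pos < 1:
        raise InputFormatError(f"positions are 1-based; got {token!r}")
    return residue, pos


@dataclass(frozen=True)
class PhosphoPSM:
    """One spectrum-level identification with localized phospho-residues."""

    spectrum_id: str
    sample_id: str
    condition: str
    protein: str
    peptide: str
    localized_sites: tuple[tuple[str, int], ...]
    flr: float

    def __post_init__(self) -> None:
        if len(self.localized_sites) < 1:
            raise InputFormatError(
                f"PSM {self.spectrum_id}: at least one localized site required"
            )
        positions = [p for _, p in self.localized_sites]
        if positions != sorted(set(positions)):
            raise InputFormatError(
                f"PSM {self.spectrum_id}: positions must be strictly increasing"
            )
        for res, _ in self.localized_sites:
            if res not in "STY":
                raise InputFormatError(
                    f"PSM {self.spectrum_id}: residue must be S/T/Y, got {res!r}"
                )
        if not 0.0 <= self.flr <= 1.0:
            raise InputFormatError(
                f"PSM {self.spectrum_id}: flr must lie in [0, 1], got {self.flr}"
            )

    @property
    def site_key(self) -> str:
        return ";".join(f"{r}{p}" for r, p in self.localized_sites)

    @property
    def site_ids(self) -> tuple[str, ...]:
        """Protein-qualified single-site identifiers, e.g. ``P00001:S263``."""
        return tuple(f"{self.protein}:{r}{p}" for r, p in self.localized_sites)


@dataclass(frozen=True)
class QuantUnit:
    """Quantification unit: (protein, peptide, localized site set)."""

    protein: str
    peptide: str
    sites: tuple[tuple[str, int], ...]

    @property
    def site_key(self) -> str:
        return ";".join(f"{r}{p}" for r, p in self.sites)

    @property
    def unit_key(self) -> str:
        return f"{self.protein}|{self.site_key}|{self.peptide}"

    @property
    def site_ids(self) -> tuple[str, ...]:
        return tuple(f"{self.protein}:{r}{p}" for r, p in self.sites)

    @property
    def multiplicity(self) -> int:
        return len(self.sites)


@dataclass
class SiteCountMatrix:
    """Spectral counts per quantification unit across samples.

    ``counts`` is indexed by unit key with one column per sample id;
    ``conditions`` maps each sample id to its condition label.
    """

    counts: pd.DataFrame
    units: dict[str, QuantUnit]
    conditions: dict[str, str]

    @property
    def multiplicity(self) -> pd.Series:
        return pd.Series(
            {k: u.multiplicity for k, u in self.units.items()},
            name="multiplicity",
        ).reindex(self.counts.index)

    @property
    def n_units(self) -> int:
        return self.counts.shape[0]

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


def parse_psm_table(path) -> list[PhosphoPSM]:
    """Read a tab-delimited PSM table into :class:`PhosphoPSM` records.

    Row order is preserved; errors name the offending 1-based data row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing:
        raise InputFormatError(f"PSM table missing column(s): {', '.join(missing)}")
    psms: list[PhosphoPSM] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            sites = tuple(
                parse_site_token(tok)
                for tok in str(getattr(row, "site_list")).split(";")
            )
            flr = float(getattr(row, "flr"))
            psms.append(
                PhosphoPSM(
                    spectrum_id=str(row.spectrum_id),
                    sample_id=str(row.sample_id),
                    condition=str(row.condition),
                    protein=str(row.protein),
                    peptide=str(row.peptide),
                    localized_sites=sites,
                    flr=flr,
                )
            )
        except (InputFormatError, TypeError) as exc:
            raise InputFormatError(f"row {i}: {exc}") from exc
    return psms


def psms_to_frame(psms: Iterable[PhosphoPSM]) -> pd.DataFrame:
    records = list(psms)
    return pd.DataFrame(
        {
            "spectrum_id": [p.spectrum_id for p in records],
            "sample_id": [p.sample_id for p in records],
            "condition": [p.condition for p in records],
            "protein": [p.protein for p in records],
            "peptide": [p.peptide for p in records],
            "site_list": [p.site_key for p in records],
            "flr": [p.flr for p in records],
        }
    )


def psms_from_frame(df: pd.DataFrame) -> list[PhosphoPSM]:
    """Convert an in-memory PSM table (as emitted by the simulator)."""
    return [
        PhosphoPSM(
            spectrum_id=str(r.spectrum_id),
            sample_id=str(r.sample_id),
            condition=str(r.condition),
            protein=str(r.protein),
            peptide=str(r.peptide),
            localized_sites=tuple(
                parse_site_token(t) for t in str(r.site_list).split(";")
            ),
            flr=float(r.flr),
        )
        for r in df.itertuples(index=False)
    ]


def filter_by_flr(
    psms: Sequence[PhosphoPSM], flr_max: float = 0.01
) -> list[PhosphoPSM]:
    """Keep PSMs whose localization FLR is at most ``flr_max`` (inclusive)."""
    if not 0.0 < flr_max <= 1.0:
        raise ParameterError(f"flr_max must lie in (0, 1], got {flr_max}")
    return [p for p in psms if p.flr <= flr_max]


def count_spectra(psms: Sequence[PhosphoPSM]) -> SiteCountMatrix:
    """Tally spectra per (protein, peptide, site set) unit and sample.

    Each PSM contributes exactly one count to exactly one unit, so column
    sums equal the per-sample PSM totals.
    """
    units: dict[str, QuantUnit] = {}
    conditions: dict[str, str] = {}
    tally: dict[tuple[str, str], int] = {}
    for p in psms:
        if len(p.localized_sites) == 0:  # pragma: no cover - blocked upstream
            raise InputFormatError(f"PSM {p.spectrum_id}: empty site list")
        unit = QuantUnit(p.protein, p.peptide, p.localized_sites)
        key = unit.unit_key
        units.setdefault(key, unit)
        prev = conditions.setdefault(p.sample_id, p.condition)
        if prev != p.condition:
            raise InputFormatError(
                f"sample {p.sample_id} maps to conflicting conditions"
            )
        tally[(key, p.sample_id)] = tally.get((key, p.sample_id), 0) + 1

    sample_ids = sorted(conditions)
    unit_keys = sorted(units)
    counts = pd.DataFrame(0, index=unit_keys, columns=sample_ids, dtype=int)
    for (key, sample), n in tally.items():
        counts.at[key, sample] = n
    return SiteCountMatrix(counts=counts, units=units, conditions=conditions)


def multiplicity_breakdown(
    matrix: SiteCountMatrix,
) -> dict[int, tuple[int, int]]:
    """Units and integer percentages per phosphosite multiplicity.

    Percentages are ``round(100 * count / total)``; an empty matrix yields
    an empty mapping.
    """
    total = matrix.n_units
    if total == 0:
        return {}
    out: dict[int, tuple[int, int]] = {}
    mult = pd.Series({k: u.multiplicity for k, u in matrix.units.items()})
    for m, cnt in mult.value_counts().sort_index().items():
        out[int(m)] = (int(cnt), int(round(100 * cnt / total)))
    return out


def collapse_to_sites(matrix: SiteCountMatrix) -> pd.DataFrame:
    """Aggregate unit counts to single residues.

    A unit's count is added to every residue it localizes, so multi-site
    units contribute to several rows.  This is a reporting view; the
    differential test operates on units.
    """
    rows: dict[str, pd.Series] = {}
    for key, unit in matrix.units.items():
        for sid in unit.site_ids:
            if sid in rows:
                rows[sid] = rows[sid] + matrix.counts.loc[key]
            else:
                rows[sid] = matrix.counts.loc[key].copy()
    if not rows:
        return pd.DataFrame(columns=matrix.counts.columns)
    return pd.DataFrame(rows).T.sort_index()


def write_matrix(matrix: SiteCountMatrix, path) -> None:
    """Emit the matrix as TSV with unit metadata + per-sample columns.

    Sample columns are written as ``condition|sample_id`` so the design is
    recoverable from the header.
    """
    meta = pd.DataFrame(
        {
            "unit_key": list(matrix.counts.index),
            "protein": [matrix.units[k].protein for k in matrix.counts.index],
            "peptide": [matrix.units[k].peptide for k in matrix.counts.index],
            "site_list": [matrix.units[k].site_key for k in matrix.counts.index],
            "multiplicity": [
                matrix.units[k].multiplicity for k in matrix.counts.index
            ],
        }
    )
    data = matrix.counts.reset_index(drop=True).rename(
        columns={s: f"{matrix.conditions[s]}|{s}" for s in matrix.counts.columns}
    )
    pd.concat([meta, data], axis=1).to_csv(path, sep="\t", index=False)


def read_matrix(path) -> SiteCountMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str, "protein": str})
    meta_cols = {"unit_key", "protein", "peptide", "site_list", "multiplicity"}
    missing = meta_cols - set(df.columns)
    if missing:
        raise InputFormatError(f"matrix missing column(s): {sorted(missing)}")
    sample_cols = [c for c in df.columns if c not in meta_cols]
    conditions: dict[str, str] = {}
    rename: dict[str, str] = {}
    for c in sample_cols:
        if "|" not in c:
            raise InputFormatError(f"sample column {c!r} lacks 'condition|sample'")
        cond, sample = c.split("|", 1)
        conditions[sample] = cond
        rename[c] = sample
    units = {
        str(r.unit_key): QuantUnit(
            str(r.protein),
            str(r.peptide),
            tuple(parse_site_token(t) for t in str(r.site_list).split(";")),
        )
        for r in df.itertuples(index=False)
    }
    counts = (
        df.set_index("unit_key")[sample_cols].rename(columns=rename).astype(int)
    )
    counts.index = counts.index.astype(str)
    counts.index.name = None
    return SiteCountMatrix(counts=counts, units=units, conditions=conditions)
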