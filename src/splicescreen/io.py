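"""Reading and writing of screen tables: plate maps, Cp tables, primer panels,
gene sets, configuration, and tidy result output.

All tables are long ("tidy") delimited text, one measurement per row.  Well
labels are plain row-letter + column-number strings (``A1`` ... ``P24``) and
are normalized to a zero-padded canonical form (``A01``) on input; they are
labels only and never used as arithmetic indices.
"""

from __future__ import annotations

import logging
import re
import tomllib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

#: column order of a tidy Cp table
CP_COLUMNS = ["plate_id", "well", "strain_id", "target_id", "bio_rep", "tech_rep", "cp"]

#: column order of a plate map
PLATE_MAP_COLUMNS = ["plate_id", "well", "strain_id", "bio_rep"]

#: tokens that mean "no amplification" in instrument exports
DEFAULT_MISSING_TOKENS = ("", "NA", "undetermined", "Undetermined")

#: 17 significant digits guarantee binary round-trip of doubles
FLOAT_FORMAT = "%.17g"

_WELL_RE = re.compile(r"^([A-Pa-p])0*([1-9]\d*)$")

ROLES = ("reference", "precursor", "total", "chip_region", "unknown")


def normalize_well(label: str) -> str:
    """Canonicalize a 384-well label: ``a1`` or ``A01`` -> ``A01``.

    Raises ``ValueError`` for anything outside A1..P24.
    """
    m = _WELL_RE.match(str(label).strip())
    if not m:
        raise ValueError(f"invalid well label: {label!r}")
    row, col = m.group(1).upper(), int(m.group(2))
    if col > 24:
        raise ValueError(f"well column out of range for a 384-well plate: {label!r}")
    return f"{row}{col:02d}"


@dataclass(frozen=True)
class PrimerPanel:
    """The set of primer pairs measured in a screen and their roles.

    roles maps target_id -> one of 'reference', 'precursor', 'total',
    'chip_region' (or 'unknown' for targets tagged at read time).
    """

    roles: dict = field(default_factory=dict)

    def __post_init__(self):
        for t, r in self.roles.items():
            if r not in ROLES:
                raise ValueError(f"unknown role {r!r} for target {t!r}")

    @property
    def targets(self) -> list:
        return list(self.roles)

    @property
    def reference_targets(self) -> list:
        return [t for t, r in self.roles.items() if r == "reference"]

    @property
    def precursor_targets(self) -> list:
        return [t for t, r in self.roles.items() if r == "precursor"]

    @property
    def total_targets(self) -> list:
        return [t for t, r in self.roles.items() if r == "total"]

    def role(self, target_id: str) -> str:
        return self.roles.get(target_id, "unknown")

    def require_references(self, min_refs: int = 1) -> None:
        if len(self.reference_targets) < min_refs:
            raise ValueError(
                f"panel declares {len(self.reference_targets)} reference "
                f"targets; at least {min_refs} required for normalization"
            )


def read_cp_table(
    path,
    panel: PrimerPanel | None = None,
    missing_tokens: tuple = DEFAULT_MISSING_TOKENS,
) -> pd.DataFrame:
    """Read a long-format Cp table into a validated record frame.

    Required columns: plate_id, well, strain_id, target_id, bio_rep,
    tech_rep, cp.  Missing / "undetermined" Cp values become NaN.  Targets
    absent from *panel* trigger a warning and are tagged role='unknown' in
    the returned ``role`` column.

    Raises
    ------
    ValueError
        on a duplicated (plate_id, well, target_id, tech_rep) key (the
        offending key is named) or on a non-numeric Cp that is not a
        declared missing token (the row number is named).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in CP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    df = df[CP_COLUMNS].copy()
    df["well"] = df["well"].map(normalize_well)
    df["tech_rep"] = df["tech_rep"].astype(int)
    if (df["tech_rep"] < 1).any():
        raise ValueError(f"{path}: tech_rep must be >= 1")

    cp = pd.Series(float("nan"), index=df.index)
    token_set = set(missing_tokens)
    for i, raw in enumerate(df["cp"]):
        s = raw.strip()
        if s in token_set:
            continue
        try:
            v = float(s)
        except ValueError:
            raise ValueError(
                f"{path}: non-numeric cp {raw!r} at data row {i + 1}"
            ) from None
        if not v > 0 or v != v or v == float("inf"):
            raise ValueError(f"{path}: cp must be finite and positive, got {v} at data row {i + 1}")
        cp.iloc[i] = v
    df["cp"] = cp

    key = ["plate_id", "well", "target_id", "tech_rep"]
    dup = df.duplicated(subset=key, keep=False)
    if dup.any():
        first = df.loc[dup, key].iloc[0]
        raise ValueError(
            f"{path}: duplicated measurement key plate={first.plate_id!r} "
            f"well={first.well!r} target={first.target_id!r} tech_rep={first.tech_rep}"
        )

    if panel is not None:
        df["role"] = df["target_id"].map(panel.role)
        unknown = sorted(df.loc[df["role"] == "unknown", "target_id"].unique())
        if unknown:
            warnings.warn(
                f"{path}: targets not in primer panel, tagged role=unknown: {unknown}",
                stacklevel=2,
            )
    logger.info("read %d Cp records from %s", len(df), path)
    return df.reset_index(drop=True)


def read_plate_map(path) -> pd.DataFrame:
    """Read a plate map: columns plate_id, well, strain_id, bio_rep.

    Empty wells may simply be absent.  A well mapped to two different
    strains is a hard error.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in PLATE_MAP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    df = df[PLATE_MAP_COLUMNS].copy()
    df["well"] = df["well"].map(normalize_well)
    key = ["plate_id", "well"]
    conflicts = df.drop_duplicates().duplicated(subset=key, keep=False)
    if conflicts.any():
        bad = df.drop_duplicates().loc[conflicts, key].iloc[0]
        raise ValueError(
            f"{path}: well {bad.well!r} on plate {bad.plate_id!r} mapped to multiple strains"
        )
    return df.drop_duplicates().reset_index(drop=True)


def read_gene_sets(path) -> dict:
    """Read gene sets from delimited text.

    Two-column rows are (set_name, member); single-column rows put every
    member in one set named after the file stem.
    """
    path = Path(path)
    sets: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in re.split(r"[,\t]", line)]
            if len(parts) == 1:
                sets.setdefault(path.stem, set()).add(parts[0])
            else:
                sets.setdefault(parts[0], set()).add(parts[1])
    return sets


def write_results(tables: dict, out_dir) -> pd.DataFrame:
    """Write one CSV per named table; return a manifest of files and row counts.

    Floats are written with 17 significant digits so that a write -> read ->
    write cycle is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for name, table in tables.items():
        fname = f"{name}.csv"
        table.to_csv(out_dir / fname, index=False, float_format=FLOAT_FORMAT)
        entries.append({"table": name, "file": fname, "n_rows": len(table)})
        logger.info("wrote %s (%d rows)", out_dir / fname, len(table))
    manifest = pd.DataFrame(entries, columns=["table", "file", "n_rows"])
    manifest.to_csv(out_dir / "MANIFEST.csv", index=False)
    return manifest


def read_table(path, **kwargs) -> pd.DataFrame:
    """Read a result table back with full floating-point precision.

    Plain ``pandas.read_csv`` uses a fast float parser that can be one ULP
    off; this wrapper forces the correctly rounded parser so that
    ``read(write(x)) == x`` holds exactly.
    """
    return pd.read_csv(path, float_precision="round_trip", **kwargs)


def load_config(path) -> dict:
    """Load a TOML configuration file (panel, filters, SAM settings)."""
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def panel_from_config(config: dict) -> PrimerPanel:
    """Build a PrimerPanel from the [panel] table of a configuration."""
    panel = config.get("panel", config)
    roles: dict[str, str] = {}
    for role_key, role in (
        ("reference_targets", "reference"),
        ("precursor_targets", "precursor"),
        ("total_targets", "total"),
        ("chip_targets", "chip_region"),
    ):
        for t in panel.get(role_key, []):
            roles[t] = role
    return PrimerPanel(roles)
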