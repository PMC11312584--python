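"""Reading, validating and writing plate-reader readout tables.

The on-disk dialect is a single long-form CSV with header
``group_id,reporter,bio_rep,tech_rep,counts``: one row per luminescence
measurement, UTF-8, comma-delimited, decimal point, scientific notation
accepted on read.  ``group_id`` is a strain gene id, the wild-type vehicle
id, an untreated-control id, or a ``compound:dose`` condition.  Reporters
are ``FF`` (Firefly, fused to the protein of interest) and ``REN``
(Renilla, the independently expressed control).

Instrument-native exports (e.g. GloMax workbooks) are out of scope; adapt
them to this dialect before ingestion.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ReadoutTable", "read_readouts", "write_readouts", "COLUMNS", "REPORTERS"]

COLUMNS = ["group_id", "reporter", "bio_rep", "tech_rep", "counts"]
REPORTERS = ("FF", "REN")

#: recognised assay variants (screen-format dual luciferase vs homogeneous
#: Dual-Glo used for compound panels; they differ only in calibration).
ASSAY_VARIANTS = ("dual_luciferase_screen", "dual_glo_compound")


@dataclass
class ReadoutTable:
    """Long-form table of luminescence readouts.

    ``df`` holds one row per measurement with the columns in :data:`COLUMNS`;
    ``assay_variant`` is carried as metadata and not persisted to CSV.
    """

    df: pd.DataFrame
    assay_variant: str = "dual_luciferase_screen"

    def __post_init__(self) -> None:
        if self.assay_variant not in ASSAY_VARIANTS:
            raise ValueError(f"unknown assay variant {self.assay_variant!r}")
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        df = self.df
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"readout table missing column(s): {', '.join(missing)}")
        df = df.loc[:, COLUMNS]

        bad_rep = ~df["reporter"].isin(REPORTERS)
        if bad_rep.any():
            rows = _rows(df, bad_rep)
            raise ValueError(f"unknown reporter value(s) at row(s) {rows}")

        for col in ("bio_rep", "tech_rep"):
            vals = df[col]
            if not np.issubdtype(vals.dtype, np.integer):
                as_float = vals.astype(float)
                if not np.all(as_float == np.round(as_float)):
                    rows = _rows(df, as_float != np.round(as_float))
                    raise ValueError(f"non-integer {col} at row(s) {rows}")
                df[col] = as_float.astype(int)
            if (df[col] < 1).any():
                rows = _rows(df, df[col] < 1)
                raise ValueError(f"{col} must be >= 1; offending row(s) {rows}")

        counts = df["counts"].astype(float)
        nonpos = ~(counts > 0) | ~np.isfinite(counts)
        if nonpos.any():
            rows = _rows(df, nonpos)
            raise ValueError(f"counts must be positive and finite; offending row(s) {rows}")
        df["counts"] = counts

        key = ["group_id", "reporter", "bio_rep", "tech_rep"]
        dup = df.duplicated(subset=key, keep=False)
        if dup.any():
            rows = _rows(df, dup)
            raise ValueError(f"duplicate (group, reporter, bio, tech) key at row(s) {rows}")

        for group, sub in df.groupby("group_id", sort=False):
            present = set(sub["reporter"])
            for rep in REPORTERS:
                if rep not in present:
                    raise ValueError(f"group {group!r} lacks {rep} records")
            for rep in REPORTERS:
                repsub = sub[sub["reporter"] == rep]
                bios = np.sort(repsub["bio_rep"].unique())
                if not np.array_equal(bios, np.arange(1, len(bios) + 1)):
                    raise ValueError(
                        f"group {group!r} reporter {rep}: bio_rep indices "
                        f"{bios.tolist()} are not contiguous from 1"
                    )
                for bio, biosub in repsub.groupby("bio_rep"):
                    techs = np.sort(biosub["tech_rep"].to_numpy())
                    if not np.array_equal(techs, np.arange(1, len(techs) + 1)):
                        raise ValueError(
                            f"group {group!r} reporter {rep} bio {bio}: tech_rep "
                            f"indices {techs.tolist()} are not contiguous from 1"
                        )
        self.df = df.reset_index(drop=True)

    # -- convenience -----------------------------------------------------
    @property
    def groups(self) -> list[str]:
        """Group ids in first-appearance order."""
        return list(dict.fromkeys(self.df["group_id"]))

    def counts_for(self, group_id: str, reporter: str) -> np.ndarray:
        sel = (self.df["group_id"] == group_id) & (self.df["reporter"] == reporter)
        return self.df.loc[sel, "counts"].to_numpy()

    def sorted_df(self) -> pd.DataFrame:
        return self.df.sort_values(
            ["group_id", "reporter", "bio_rep", "tech_rep"], kind="mergesort"
        ).reset_index(drop=True)

    def equals(self, other: "ReadoutTable") -> bool:
        return self.assay_variant == other.assay_variant and self.sorted_df().equals(
            other.sorted_df()
        )

    def __len__(self) -> int:
        return len(self.df)


def _rows(df: pd.DataFrame, mask) -> list[int]:
    """1-based data-row numbers (header is row 0) for error messages."""
    return (np.flatnonzero(np.asarray(mask)) + 1).tolist()


def write_readouts(table: ReadoutTable, path: str | Path) -> Path:
    """Write a table in the canonical dialect.

    Rows are sorted by (group, reporter, bio, tech) so output is
    byte-identical across runs for the same table.
    """
    path = Path(path)
    out = table.sorted_df()
    with path.open("w", newline="", encoding="utf-8") as fh:
        # %.17g round-trips every float64 exactly
        out.to_csv(fh, index=False, lineterminator="\n", float_format="%.17g")
    return path


def read_readouts(
    path: str | Path, assay_variant: str = "dual_luciferase_screen"
) -> ReadoutTable:
    """Read and validate a readout CSV.

    Raises ``FileNotFoundError`` for a missing file and ``ValueError`` for a
    malformed one (missing columns, duplicate keys, non-positive counts,
    groups missing a reporter, non-contiguous replicate indices).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing column(s): {', '.join(missing)}")
    if len(df) == 0:
        return ReadoutTable(
            df=pd.DataFrame(
                {
                    "group_id": pd.Series(dtype=str),
                    "reporter": pd.Series(dtype=str),
                    "bio_rep": pd.Series(dtype=int),
                    "tech_rep": pd.Series(dtype=int),
                    "counts": pd.Series(dtype=float),
                }
            ),
            assay_variant=assay_variant,
        )
    df["group_id"] = df["group_id"].astype(str)
    df["reporter"] = df["reporter"].astype(str)
    return ReadoutTable(df=df, assay_variant=assay_variant)
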