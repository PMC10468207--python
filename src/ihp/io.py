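"""Tabular and image I/O.

All tabular outputs are tab-separated with a commented header naming the
units and conventions (1-based residue numbering, kDa, minutes); mass
event lists are single-column CSV; images round-trip through TIFF.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synth import ImagePair, MassEventList

_TIMECOURSE_HEADER = (
    "# phospho time course: conc_nM (enzyme concentration, nM), "
    "time_min (minutes), replicate, phospho / total (signal, a.u.)\n"
)
_XL_HEADER = (
    "# crosslink table: positions 1-based protein numbering; "
    "I_* are MS1 channel intensities (L=14N, H=15N), a.u.; incubation in minutes\n"
)


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_timecourse(table: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(_TIMECOURSE_HEADER)
        table.to_csv(fh, sep="\t", index=False)


def read_timecourse(path) -> pd.DataFrame:
    table = _read_tsv(path)
    missing = {"conc_nM", "time_min", "replicate", "phospho", "total"} - set(table.columns)
    if missing:
        raise ValueError(f"timecourse table {path} missing columns {sorted(missing)}")
    return table


def write_xl_table(table: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(_XL_HEADER)
        table.to_csv(fh, sep="\t", index=False)


#: Default mapping from pLink2-style report columns to internal names.
PLINK_COLUMN_MAP = {
    "Peptide1": "pep_a",
    "Peptide2": "pep_b",
    "Position1": "pos_a",
    "Position2": "pos_b",
    "Replicate": "replicate",
    "Condition": "condition",
    "Incubation": "incubation",
    "I_14N14N": "I_LL",
    "I_14N15N": "I_LH",
    "I_15N14N": "I_HL",
    "I_15N15N": "I_HH",
}


def read_xl_table(path, column_map: dict[str, str] | None = None, sep: str | None = None) -> pd.DataFrame:
    """Read a crosslink table (internal TSV or pLink2-style CSV).

    ``column_map`` renames source columns to the internal schema; the
    default handles both the internal names and pLink2-style labels.
    """
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    table = pd.read_csv(path, sep=sep, comment="#")
    table = table.rename(columns=column_map or PLINK_COLUMN_MAP)
    required = {"pos_a", "pos_b", "replicate", "I_LL", "I_LH", "I_HL", "I_HH"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"crosslink table {path} missing columns {sorted(missing)}")
    return table


def write_mass_events(events: MassEventList, path) -> None:
    pd.DataFrame({"mass_kDa": events.masses}).to_csv(path, index=False)


def read_mass_events(path, condition: str | None = None) -> MassEventList:
    table = pd.read_csv(path, comment="#")
    col = "mass_kDa" if "mass_kDa" in table.columns else table.columns[0]
    masses = table[col].to_numpy(float)
    return MassEventList(masses=masses, labels=np.full(len(masses), -1),
                         condition=condition)


def write_image_pair(pair: ImagePair, path_1, path_2) -> None:
    tifffile.imwrite(path_1, pair.channel_1.astype(np.float32))
    tifffile.imwrite(path_2, pair.channel_2.astype(np.float32))


def read_image_pair(path_1, path_2) -> ImagePair:
    ch1 = tifffile.imread(path_1).astype(float)
    ch2 = tifffile.imread(path_2).astype(float)
    return ImagePair(channel_1=ch1, channel_2=ch2,
                     centers_1=np.empty((0, 2)), centers_2=np.empty((0, 2)))


def write_json_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
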