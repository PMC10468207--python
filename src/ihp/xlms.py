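"""Quantitative mixed-isotope crosslinking-MS analysis.

Crosslinked peptide pairs from a 1:1 mix of normal (light, 14N) and
metabolically 15N-labelled (heavy) holoenzymes occupy four MS1 channels:
light:light, light:heavy, heavy:light and heavy:heavy.  Homotypic
(uni-isotopic) channels report contacts within one preparation — in a
stable holoenzyme, almost always intra-holoenzyme contacts — while
heterotypic (mixed-isotope) channels can only arise from contact between
subunits of differently labelled holoenzymes, either through subunit
exchange or through transient inter-holoenzyme association.

The per-crosslink mixing ratio

    R = (I_LH + I_HL) / (I_LL + I_HH)

and the domain-pair profile of heterotypic crosslinks discriminate the two
mechanisms: subunit exchange predicts heterotypic crosslinks across all
domain pairs (hub-hub included), inter-holoenzyme phosphorylation predicts
them confined to kinase-kinase contacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from pyteomics import mass as _pmass

logger = logging.getLogger(__name__)

INTENSITY_COLUMNS = ("I_LL", "I_LH", "I_HL", "I_HH")

#: Standard 15N-14N monoisotopic mass difference per nitrogen atom (Da).
N15_SHIFT_PER_N = 0.997035


@dataclass(frozen=True)
class MassConstants:
    """Crosslinker mass bookkeeping constants (Da).

    ``linker_mass`` is the mass added by a DSS crosslink joining two
    peptides; ``mono_mass`` the mass of a hydrolysed mono-link (stored for
    completeness, mono-links are not quantified here).
    """

    linker_mass: float = 138.068
    mono_mass: float = 156.079
    n15_shift_per_n: float = N15_SHIFT_PER_N


DEFAULT_MASS_CONSTANTS = MassConstants()


class DomainMap:
    """Ordered, disjoint, contiguous named residue ranges of one subunit.

    Ranges are 1-based inclusive and must jointly cover the analyzed span
    without gaps or overlap.
    """

    def __init__(self, ranges: Mapping[str, tuple[int, int]]):
        items = list(ranges.items())
        if not items:
            raise ValueError("domain map needs at least one range")
        prev_end = None
        for name, (start, end) in items:
            if start > end:
                raise ValueError(f"domain {name!r}: start {start} > end {end}")
            if prev_end is not None and start != prev_end + 1:
                raise ValueError(
                    f"domain {name!r} starts at {start}, expected {prev_end + 1} "
                    "(ranges must be ordered and contiguous)"
                )
            prev_end = end
        self._ranges = dict(items)

    @property
    def ranges(self) -> dict[str, tuple[int, int]]:
        return dict(self._ranges)

    @property
    def names(self) -> list[str]:
        return list(self._ranges)

    @property
    def span(self) -> tuple[int, int]:
        starts = [s for s, _ in self._ranges.values()]
        ends = [e for _, e in self._ranges.values()]
        return min(starts), max(ends)

    def classify(self, pos: int) -> str:
        for name, (start, end) in self._ranges.items():
            if start <= pos <= end:
                return name
        lo, hi = self.span
        raise ValueError(f"residue {pos} outside mapped span [{lo}, {hi}]")

    def __eq__(self, other) -> bool:
        return isinstance(other, DomainMap) and self._ranges == other._ranges

    def __repr__(self) -> str:
        inner = ", ".join(f"{n}={r}" for n, r in self._ranges.items())
        return f"DomainMap({inner})"


#: Default CaMKII-alpha subunit domain boundaries (1-based, inclusive),
#: chosen so the frequently observed K344/K347 hub-hub crosslink sites
#: classify as hub.
DEFAULT_DOMAIN_MAP = DomainMap(
    {
        "kinase": (1, 274),
        "regulatory": (275, 314),
        "linker": (315, 343),
        "hub": (344, 478),
    }
)


@dataclass
class XlQuant:
    """Mixing-ratio quantification of one crosslink record."""

    R: float
    defined: bool
    domain_pair: tuple[str, str] | None = None
    is_heterotypic: bool | None = None


def nitrogen_count(peptide: str) -> int:
    """Total nitrogen atoms of a peptide (backbone + side chains).

    Termini add only H2O, which contributes no nitrogen.
    """
    if not peptide:
        raise ValueError("empty peptide sequence")
    for ch in peptide:
        if ch not in _pmass.std_aa_comp:
            raise ValueError(f"unknown residue {ch!r} in peptide {peptide!r}")
    return int(_pmass.Composition(sequence=peptide).get("N", 0))


def peptide_mono_mass(peptide: str) -> float:
    """Neutral monoisotopic mass of an unmodified peptide (Da)."""
    for ch in peptide:
        if ch not in _pmass.std_aa_comp:
            raise ValueError(f"unknown residue {ch!r} in peptide {peptide!r}")
    return float(_pmass.calculate_mass(sequence=peptide, monoisotopic=True))


@dataclass(frozen=True)
class ChannelMasses:
    """Neutral monoisotopic masses of the four isotope channels (Da)."""

    m_ll: float
    m_lh: float
    m_hl: float
    m_hh: float


def channel_masses(
    pep_a: str, pep_b: str, constants: MassConstants = DEFAULT_MASS_CONSTANTS
) -> ChannelMasses:
    """Expected masses of the four isotope channels of a crosslinked pair.

    The light:light species is the sum of the two intact neutral peptide
    masses plus the linker mass.  Heavy channels add the full 15N shift of
    the corresponding peptide (complete incorporation assumed; channel
    index HL means pep_a heavy).
    """
    m_ll = peptide_mono_mass(pep_a) + peptide_mono_mass(pep_b) + constants.linker_mass
    shift_a = constants.n15_shift_per_n * nitrogen_count(pep_a)
    shift_b = constants.n15_shift_per_n * nitrogen_count(pep_b)
    return ChannelMasses(
        m_ll=m_ll,
        m_lh=m_ll + shift_b,
        m_hl=m_ll + shift_a,
        m_hh=m_ll + shift_a + shift_b,
    )


def mixing_ratio(
    i_ll: float, i_lh: float, i_hl: float, i_hh: float,
    denominator: str = "homotypic_sum",
) -> float:
    """Scalar heterotypic/homotypic mixing ratio R.

    ``homotypic_sum`` (default) uses the uni-isotopic channels in the
    denominator, R = (I_LH + I_HL) / (I_LL + I_HH).  ``as_printed``
    reproduces the alternative denominator (I_LL + I_LH).  Returns NaN
    when the denominator is zero.
    """
    if denominator == "homotypic_sum":
        den = i_ll + i_hh
    elif denominator == "as_printed":
        den = i_ll + i_lh
    else:
        raise ValueError(f"unknown denominator variant {denominator!r}")
    if den <= 0:
        return float("nan")
    return (i_lh + i_hl) / den


def compute_R(
    rec: Mapping,
    denominator: str = "homotypic_sum",
    domain_map: DomainMap | None = None,
    hetero_floor: float = 0.0,
) -> XlQuant:
    """Quantify one crosslink record.

    ``rec`` is any mapping (dict, pandas row) with the four intensity
    fields and optionally ``pos_a``/``pos_b`` for domain classification.
    """
    r = mixing_ratio(
        rec["I_LL"], rec["I_LH"], rec["I_HL"], rec["I_HH"], denominator=denominator
    )
    pair = None
    if domain_map is not None and "pos_a" in rec and "pos_b" in rec:
        pair = domain_pair(rec["pos_a"], rec["pos_b"], domain_map)
    hetero = bool(rec["I_LH"] > hetero_floor or rec["I_HL"] > hetero_floor)
    return XlQuant(R=r, defined=np.isfinite(r), domain_pair=pair, is_heterotypic=hetero)


def classify_domain(pos: int, domain_map: DomainMap = DEFAULT_DOMAIN_MAP) -> str:
    """Domain name containing 1-based residue ``pos``."""
    return domain_map.classify(pos)


def domain_pair(
    pos_a: int, pos_b: int, domain_map: DomainMap = DEFAULT_DOMAIN_MAP
) -> tuple[str, str]:
    """Unordered domain pair of a crosslink, canonically ordered by the map."""
    a = domain_map.classify(pos_a)
    b = domain_map.classify(pos_b)
    order = {n: i for i, n in enumerate(domain_map.names)}
    return (a, b) if order[a] <= order[b] else (b, a)


def quantify(
    records: pd.DataFrame,
    denominator: str = "homotypic_sum",
    domain_map: DomainMap = DEFAULT_DOMAIN_MAP,
    hetero_floor: float = 0.0,
) -> pd.DataFrame:
    """Vectorised quantification of a crosslink table.

    Adds columns ``R`` (NaN where undefined), ``R_defined``, ``domain_a``,
    ``domain_b``, ``domain_pair`` and ``is_heterotypic``; undefined-R
    records are retained but flagged, and their count is logged.
    """
    out = records.copy()
    ll, lh, hl, hh = (out[c].to_numpy(float) for c in INTENSITY_COLUMNS)
    if denominator == "homotypic_sum":
        den = ll + hh
    elif denominator == "as_printed":
        den = ll + lh
    else:
        raise ValueError(f"unknown denominator variant {denominator!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(den > 0, (lh + hl) / den, np.nan)
    out["R"] = r
    out["R_defined"] = np.isfinite(r)
    n_undef = int((~out["R_defined"]).sum())
    if n_undef:
        logger.warning("%d crosslink records have undefined R (zero denominator)", n_undef)
    out["domain_a"] = [domain_map.classify(p) for p in out["pos_a"]]
    out["domain_b"] = [domain_map.classify(p) for p in out["pos_b"]]
    out["domain_pair"] = [
        "-".join(domain_pair(a, b, domain_map))
        for a, b in zip(out["pos_a"], out["pos_b"])
    ]
    out["is_heterotypic"] = (lh > hetero_floor) | (hl > hetero_floor)
    return out


def build_heatmap(
    records: pd.DataFrame,
    mode: str = "heterotypic",
    require_both_replicates: bool = True,
    domain_map: DomainMap = DEFAULT_DOMAIN_MAP,
    hetero_floor: float = 0.0,
) -> pd.DataFrame:
    """Domain-pair count matrix of unique crosslink site pairs.

    A crosslink site pair is the unordered (pos_a, pos_b) tuple, so peptide
    variants (missed cleavages) collapse onto one site pair.  A pair counts
    as heterotypic when its mixed-isotope channels are detected (above
    ``hetero_floor``) in every replicate in which it appears; otherwise it
    is homotypic.  With ``require_both_replicates`` only pairs observed in
    all replicates are counted, once.

    The returned matrix is indexed by domain names in map order; each
    unordered domain pair is counted once, in its canonical (upper
    triangle) cell, so the matrix total equals the number of counted
    crosslinks.
    """
    if mode not in ("heterotypic", "homotypic"):
        raise ValueError(f"unknown heatmap mode {mode!r}")
    names = domain_map.names
    matrix = pd.DataFrame(0, index=names, columns=names, dtype=int)
    if records.empty:
        return matrix

    reps = sorted(records["replicate"].unique())
    if require_both_replicates and len(reps) < 2:
        raise ValueError(
            f"replicate intersection requires >=2 replicate labels, found {reps}"
        )

    work = records.copy()
    work["_key"] = [
        (min(a, b), max(a, b)) for a, b in zip(work["pos_a"], work["pos_b"])
    ]
    work["_hetero"] = (work["I_LH"] > hetero_floor) | (work["I_HL"] > hetero_floor)

    per_key = work.groupby("_key").agg(
        n_reps=("replicate", "nunique"),
        hetero_all=("_hetero", "all"),
    )
    if require_both_replicates:
        per_key = per_key[per_key["n_reps"] == len(reps)]

    keys = per_key[per_key["hetero_all"] == (mode == "heterotypic")].index
    for pos_a, pos_b in keys:
        a, b = domain_pair(pos_a, pos_b, domain_map)
        matrix.loc[a, b] += 1
    return matrix


def summarize_ratios(
    quantified: pd.DataFrame, group_by: str = "domain_pair"
) -> pd.DataFrame:
    """Mean R +/- standard error per group, with counts.

    Undefined-R records are excluded from the means (their count is
    logged); groups with no defined R are omitted.
    """
    if "R" not in quantified.columns:
        raise ValueError("input is not quantified; run quantify() first")
    defined = quantified[np.isfinite(quantified["R"])]
    n_excluded = len(quantified) - len(defined)
    if n_excluded:
        logger.info("summarize_ratios: excluded %d undefined-R records", n_excluded)
    rows = []
    for key, grp in defined.groupby(group_by):
        r = grp["R"].to_numpy(float)
        se = float(np.std(r, ddof=1) / np.sqrt(len(r))) if len(r) > 1 else 0.0
        rows.append({group_by: key, "mean_R": float(np.mean(r)), "se_R": se, "n": len(r)})
    return pd.DataFrame(rows, columns=[group_by, "mean_R", "se_R", "n"])


# ---------------------------------------------------------------------------
# structure mapping

def load_ca_coordinates(pdb_path: str) -> dict[str, dict[int, np.ndarray]]:
    """C-alpha coordinates per chain from a PDB file.

    Returns ``{chain_id: {residue_number: xyz}}`` in Angstroms.
    """
    from biotite.structure.io.pdb import PDBFile

    structure = PDBFile.read(pdb_path).get_structure(model=1)
    ca = structure[structure.atom_name == "CA"]
    coords: dict[str, dict[int, np.ndarray]] = {}
    for atom in ca:
        coords.setdefault(str(atom.chain_id), {})[int(atom.res_id)] = np.asarray(
            atom.coord, dtype=float
        )
    return coords


PAIRINGS = ("intra_subunit", "inter_subunit_min", "inter_holoenzyme_min")


def map_to_structure(
    records: pd.DataFrame,
    coordinates: dict[str, dict[int, np.ndarray]],
    pairing: str = "inter_subunit_min",
    max_dist: float = 30.0,
    coordinates_b: dict[str, dict[int, np.ndarray]] | None = None,
    numbering_offset: int = 0,
    pseudobond_path: str | None = None,
) -> pd.DataFrame:
    """Minimal C-alpha distance of each crosslink over allowed chain pairs.

    ``pairing`` selects which chain pairs are admissible: within one chain
    (``intra_subunit``), across distinct chains of one assembly
    (``inter_subunit_min``), or across two assemblies
    (``inter_holoenzyme_min``; pass the second assembly's coordinates as
    ``coordinates_b``, e.g. a rigid-body-placed copy).  ``numbering_offset``
    is added to record positions to reconcile construct and structure
    numbering.  A link whose residues are absent from the coordinates is
    flagged unmapped, never dropped.

    Optionally writes a pseudobond file (one ``/chain:res@CA`` pair per
    line) for structure viewers.
    """
    if pairing not in PAIRINGS:
        raise ValueError(f"unknown pairing {pairing!r}; expected one of {PAIRINGS}")
    coords_a = coordinates
    if pairing == "inter_holoenzyme_min":
        coords_b = coordinates_b if coordinates_b is not None else coordinates
    else:
        coords_b = coordinates

    rows = []
    pb_lines = []
    seen_keys = set()
    for _, rec in records.iterrows():
        pos_a = int(rec["pos_a"]) + numbering_offset
        pos_b = int(rec["pos_b"]) + numbering_offset
        key = (min(pos_a, pos_b), max(pos_a, pos_b))
        best = None
        for ch_a, res_a in coords_a.items():
            if pos_a not in res_a:
                continue
            for ch_b, res_b in coords_b.items():
                if pos_b not in res_b:
                    continue
                if pairing == "intra_subunit" and ch_a != ch_b:
                    continue
                if (
                    pairing == "inter_subunit_min"
                    and coords_b is coords_a
                    and ch_a == ch_b
                ):
                    continue
                d = float(np.linalg.norm(res_a[pos_a] - res_b[pos_b]))
                if best is None or d < best[0]:
                    best = (d, ch_a, ch_b)
        if best is None:
            rows.append(
                {
                    "pos_a": pos_a, "pos_b": pos_b, "distance": np.nan,
                    "satisfied": False, "mapped": False,
                    "chain_a": None, "chain_b": None,
                }
            )
            logger.warning("crosslink (%d, %d) unmapped in coordinates", pos_a, pos_b)
            continue
        d, ch_a, ch_b = best
        rows.append(
            {
                "pos_a": pos_a, "pos_b": pos_b, "distance": d,
                "satisfied": bool(d <= max_dist), "mapped": True,
                "chain_a": ch_a, "chain_b": ch_b,
            }
        )
        if key not in seen_keys:
            pb_lines.append(f"/{ch_a}:{pos_a}@CA /{ch_b}:{pos_b}@CA")
            seen_keys.add(key)
    out = pd.DataFrame(
        rows,
        columns=["pos_a", "pos_b", "distance", "satisfied", "mapped", "chain_a", "chain_b"],
    )
    if pseudobond_path is not None:
        with open(pseudobond_path, "w") as fh:
            fh.write("; crosslink pseudobonds, C-alpha to C-alpha\n")
            fh.write("\n".join(pb_lines) + ("\n" if pb_lines else ""))
    return out
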