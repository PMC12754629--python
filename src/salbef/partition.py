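"""Additive partitioning of net biodiversity effects (Loreau–Hector).

For a mixture of ``N`` species with monoculture yields ``M_i``, expected
relative yields ``RY_E,i`` (the inoculated proportions) and observed mixture
yields ``Y_O,i``, the net biodiversity effect decomposes exactly:

    NBE = Y_O - Y_E = sum_i dRY_i * M_i
        = N * mean(dRY) * mean(M)        (complementarity effect, CE)
        + N * cov(dRY, M)                (selection effect, SE)

with ``dRY_i = Y_O,i / M_i - RY_E,i`` and the *population* covariance (1/N
normalizer) — only that normalizer makes CE + SE = NBE an identity.

Species that do not grow in monoculture (``M_i`` at or below the detection
floor) are excluded before partitioning and the inoculated proportions are
renormalized over the retained species: ``RY_O,i = Y_O,i / M_i`` diverges as
``M_i -> 0`` and would dominate the covariance artifactually.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import UnmappedTaxonError

__all__ = [
    "PartitionInput",
    "PartitionResult",
    "ExclusionReport",
    "expected_yield",
    "relative_yields",
    "partition",
    "abundance_to_member_yields",
    "filter_viable_species",
    "partition_experiment",
    "partition_from_composition",
    "genus_strain_map",
]


@dataclass
class PartitionInput:
    """Aligned per-species vectors for one mixture x salinity."""

    m: np.ndarray
    ry_expected: np.ndarray
    y_observed: np.ndarray
    strain_ids: tuple | None = None

    def __post_init__(self):
        self.m = np.asarray(self.m, dtype=float)
        self.ry_expected = np.asarray(self.ry_expected, dtype=float)
        self.y_observed = np.asarray(self.y_observed, dtype=float)
        n = len(self.m)
        if n == 0:
            raise ValueError("PartitionInput needs at least one species")
        if len(self.ry_expected) != n or len(self.y_observed) != n:
            raise ValueError("m, ry_expected and y_observed must have equal length")
        if np.any(self.m <= 0):
            raise ValueError("all monoculture yields must be > 0; filter non-growers first")
        if np.any(self.y_observed < 0):
            raise ValueError("observed mixture yields must be >= 0")
        if abs(math.fsum(self.ry_expected.tolist()) - 1.0) > 1e-12:
            raise ValueError("expected relative yields must sum to 1")

    @property
    def n(self) -> int:
        return len(self.m)


@dataclass
class PartitionResult:
    """One mixture's decomposition: NBE = CE + SE, with signed contributions."""

    y_o: float
    y_e: float
    nbe: float
    ce: float
    se: float
    n: int
    n_excluded: int = 0
    contribution_se_pct: float = float("nan")
    contribution_ce_pct: float = float("nan")
    opposite_signs: bool = False
    ok: bool = True
    reason: str | None = None


@dataclass
class ExclusionReport:
    """Which species the viability filter dropped, and why."""

    retained: tuple = ()
    excluded: tuple = ()
    salinity: float | None = None
    floor: float = 0.0
    reason: str | None = None

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


def expected_yield(m, ry_expected) -> float:
    """Expected mixture yield Y_E = sum_i RY_E,i * M_i (inoculation-weighted
    average of the monoculture yields)."""
    m = np.asarray(m, dtype=float)
    ry = np.asarray(ry_expected, dtype=float)
    if m.shape != ry.shape:
        raise ValueError(f"length mismatch: M has {m.shape}, RY_E has {ry.shape}")
    if abs(math.fsum(ry.tolist()) - 1.0) > 1e-12:
        raise ValueError("expected relative yields must sum to 1")
    return float(m @ ry)


def relative_yields(inp: PartitionInput):
    """Observed relative yields and their deviations.

    Returns ``(ry_observed, d_ry)`` with ``RY_O,i = Y_O,i / M_i`` and
    ``dRY_i = RY_O,i - RY_E,i``.
    """
    ry_o = inp.y_observed / inp.m
    return ry_o, ry_o - inp.ry_expected


def partition(inp: PartitionInput) -> PartitionResult:
    """Decompose one mixture's net biodiversity effect into CE and SE.

    ``CE = N * mean(dRY) * mean(M)`` and ``SE = N * cov_pop(dRY, M)``; the
    additivity identity ``CE + SE = NBE`` then holds to floating-point
    precision. Signed percentage contributions (100*component/NBE) are
    reported when NBE is nonzero; when CE and SE have opposite signs one
    contribution exceeds 100% and ``opposite_signs`` is flagged.
    """
    n = inp.n
    _, d_ry = relative_yields(inp)
    y_o = float(inp.y_observed.sum())
    y_e = expected_yield(inp.m, inp.ry_expected)
    nbe = y_o - y_e

    ce = n * float(d_ry.mean()) * float(inp.m.mean())
    se = 0.0 if n == 1 else n * float(np.cov(d_ry, inp.m, ddof=0)[0, 1])

    result = PartitionResult(y_o=y_o, y_e=y_e, nbe=nbe, ce=ce, se=se, n=n)
    if nbe != 0.0:
        result.contribution_se_pct = 100.0 * se / nbe
        result.contribution_ce_pct = 100.0 * ce / nbe
        result.opposite_signs = (se * ce) < 0
    return result


def genus_strain_map(design, library) -> dict:
    """Genus label -> tuple of that genus's strain ids among the design members."""
    genus_of = {p.strain_id: p.genus for p in library}
    out: dict = {}
    for sid in design.members:
        out.setdefault(genus_of[sid], []).append(sid)
    return {g: tuple(sids) for g, sids in out.items()}


def abundance_to_member_yields(
    rel_abundance: dict,
    y_o: float,
    genus_map: dict,
    mono_yields: dict,
    rule: str = "monoculture",
) -> dict:
    """Convert genus-level relative abundances into per-strain observed yields.

    Each genus receives ``proportion * Y_O``; congeneric strains split their
    genus's yield proportionally to their monoculture yields at this salinity
    (``rule="monoculture"``, the maximum-information default) or equally
    (``rule="equal"``; also the fallback when all congeners have zero
    monoculture yield). The output sums to ``Y_O``.
    """
    if rule not in ("monoculture", "equal"):
        raise ValueError(f"unknown split rule {rule!r}")
    total = math.fsum(rel_abundance.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"relative abundances must sum to 1 (got {total!r})")
    unmapped = [g for g in rel_abundance if g not in genus_map]
    if unmapped:
        raise UnmappedTaxonError(unmapped)

    out: dict = {}
    for genus, proportion in rel_abundance.items():
        strains = genus_map[genus]
        genus_yield = proportion * y_o
        weights = np.array([mono_yields.get(sid, 0.0) for sid in strains], dtype=float)
        if rule == "equal" or weights.sum() <= 0:
            weights = np.ones(len(strains))
        weights = weights / weights.sum()
        for sid, w in zip(strains, weights):
            out[sid] = out.get(sid, 0.0) + float(genus_yield * w)
    return out


def filter_viable_species(
    design,
    monocultures: pd.DataFrame | dict,
    salinity: float,
    floor: float,
    member_yields: dict,
):
    """Build a :class:`PartitionInput` from a design, dropping non-growers.

    Species with monoculture yield at or below ``floor`` at this salinity are
    excluded; expected relative yields are renormalized over the retained
    species, whose count becomes the partition's N. Observed yields of
    excluded species (zero, up to noise, under the generative model) are
    dropped. Returns ``(PartitionInput | None, ExclusionReport)``; the input
    is None when every species is excluded (functional collapse).
    """
    salinity = float(salinity)
    if isinstance(monocultures, pd.DataFrame):
        sub = monocultures[monocultures.salinity_pct == salinity]
        mono = dict(zip(sub.strain_id, sub["yield"]))
    else:
        mono = {
            sid: m
            for (sid, s), m in monocultures.items()
            if s == salinity
        }
    missing = [sid for sid in design.members if sid not in mono]
    if missing:
        raise ValueError(f"no monoculture rows at salinity {salinity} for {missing}")

    retained = [sid for sid in design.members if mono[sid] > floor]
    excluded = [sid for sid in design.members if mono[sid] <= floor]
    report = ExclusionReport(
        retained=tuple(retained), excluded=tuple(excluded), salinity=salinity, floor=floor
    )
    if not retained:
        report.reason = "all member species below the detection floor at this salinity"
        return None, report

    ry = np.array([design.ry_expected[sid] for sid in retained], dtype=float)
    inp = PartitionInput(
        m=np.array([mono[sid] for sid in retained], dtype=float),
        ry_expected=ry / ry.sum(),
        y_observed=np.array([member_yields.get(sid, 0.0) for sid in retained], dtype=float),
        strain_ids=tuple(retained),
    )
    return inp, report


def _result_row(cid, salinity, res: PartitionResult, report: ExclusionReport | None):
    n_exc = report.n_excluded if report is not None else res.n_excluded
    return {
        "community_id": cid,
        "salinity_pct": salinity,
        "N_retained": res.n if res.ok else 0,
        "Y_O": res.y_o,
        "Y_E": res.y_e,
        "NBE": res.nbe,
        "SE": res.se,
        "CE": res.ce,
        "contribution_SE_pct": res.contribution_se_pct,
        "contribution_CE_pct": res.contribution_ce_pct,
        "n_excluded": n_exc,
        "note": res.reason or "",
    }


def _impossible_row(cid, salinity, report: ExclusionReport):
    nan = float("nan")
    return {
        "community_id": cid,
        "salinity_pct": salinity,
        "N_retained": 0,
        "Y_O": nan,
        "Y_E": nan,
        "NBE": nan,
        "SE": nan,
        "CE": nan,
        "contribution_SE_pct": nan,
        "contribution_CE_pct": nan,
        "n_excluded": report.n_excluded,
        "note": report.reason or "partition impossible",
    }


def partition_experiment(
    designs: list,
    monocultures: pd.DataFrame,
    member_yields: pd.DataFrame,
    floor: float = 0.0,
) -> pd.DataFrame:
    """Partition every (community, salinity) with per-strain observed yields.

    Returns the long partition table (one row per mixture x salinity);
    collapsed mixtures (no retained species) carry NaN effects and a note.
    """
    by_design = {d.community_id: d for d in designs}
    rows = []
    for (cid, salinity), grp in member_yields.groupby(["community_id", "salinity_pct"]):
        design = by_design.get(cid)
        if design is None:
            raise ValueError(f"member_yields references unknown community {cid!r}")
        yields = dict(zip(grp.strain_id, grp["yield"]))
        inp, report = filter_viable_species(design, monocultures, salinity, floor, yields)
        if inp is None:
            rows.append(_impossible_row(cid, salinity, report))
            continue
        rows.append(_result_row(cid, salinity, partition(inp), report))
    return pd.DataFrame(rows).sort_values(["community_id", "salinity_pct"]).reset_index(drop=True)


def partition_from_composition(
    designs: list,
    library: list,
    monocultures: pd.DataFrame,
    observations: pd.DataFrame,
    composition: pd.DataFrame,
    floor: float = 0.0,
    rule: str = "monoculture",
) -> pd.DataFrame:
    """Partition mixtures whose membership is observed as genus abundances.

    This is the route used for the highest-diversity communities, where
    per-strain yields are not measured directly: genus relative abundances
    times the observed total yield give genus yields, split across congeneric
    strains by ``rule``, then partitioned as usual.
    """
    by_design = {d.community_id: d for d in designs}
    totals = {
        (r.community_id, r.salinity_pct): r.Y_O for r in observations.itertuples(index=False)
    }
    rows = []
    for (cid, salinity), grp in composition.groupby(["community_id", "salinity_pct"]):
        design = by_design.get(cid)
        if design is None:
            raise ValueError(f"composition references unknown community {cid!r}")
        y_o = totals.get((cid, salinity))
        if y_o is None:
            raise ValueError(f"no observed total yield for {cid!r} at salinity {salinity}")
        gmap = genus_strain_map(design, library)
        sub = monocultures[monocultures.salinity_pct == salinity]
        mono = dict(zip(sub.strain_id, sub["yield"]))
        yields = abundance_to_member_yields(
            dict(zip(grp.genus, grp.proportion)), y_o, gmap, mono, rule=rule
        )
        inp, report = filter_viable_species(design, monocultures, salinity, floor, yields)
        if inp is None:
            rows.append(_impossible_row(cid, salinity, report))
            continue
        rows.append(_result_row(cid, salinity, partition(inp), report))
    return pd.DataFrame(rows).sort_values(["community_id", "salinity_pct"]).reset_index(drop=True)
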