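"""ComboScore synergy labels and combination-screen I/O.

The ComboScore quantifies the benefit of a drug pair over Bliss-independence
additivity across a dose–response grid.  For a single concentration pair
with single-agent percent growths ``y_a`` and ``y_b`` (both ≤ 100, negative
values meaning net cell kill), the expected additive growth is

    expected = y_a * y_b / 100        if y_a > 0 and y_b > 0
    expected = min(y_a, y_b)          otherwise

and the score of a grid is the sum over all concentration pairs of
``expected − observed`` after truncating every growth value into
[−100, 100].  Positive scores indicate synergy, negative antagonism, and a
grid measured exactly at additivity scores 0.

The reader/writer speak the "ComboDrugGrowth" CSV dialect of the public
NCI-ALMANAC release: one row per measured well, combination rows carrying
both drug ids and single-agent rows only the first.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

KNOWN_CENTERS = ("1A", "FF", "FG")

#: Mandatory columns of the ComboDrugGrowth CSV dialect.
CSV_COLUMNS = [
    "SCREENER",
    "TESTDATE",
    "CELLNAME",
    "NSC1",
    "CONC1",
    "NSC2",
    "CONC2",
    "PERCENTGROWTH",
]
OPTIONAL_COLUMNS = ["SCORE"]


@dataclass
class DoseResponseGrid:
    """Raw percent-growth measurements for one (drug A, drug B, cell line).

    ``growth_a``/``growth_b`` are the single-agent growths at ``conc_a``/
    ``conc_b``; ``growth_combo[i][j]`` is the combination growth at
    (conc_a[i], conc_b[j]).  Growth follows PERCENTGROWTH semantics
    (≤ 100; negative for net kill).
    """

    drug_a: str
    drug_b: str
    cell_line: str
    center: str
    conc_a: np.ndarray
    conc_b: np.ndarray
    growth_a: np.ndarray
    growth_b: np.ndarray
    growth_combo: np.ndarray
    test_date: str = ""

    def __post_init__(self) -> None:
        self.conc_a = np.asarray(self.conc_a, dtype=float)
        self.conc_b = np.asarray(self.conc_b, dtype=float)
        self.growth_a = np.asarray(self.growth_a, dtype=float)
        self.growth_b = np.asarray(self.growth_b, dtype=float)
        self.growth_combo = np.asarray(self.growth_combo, dtype=float)
        if (self.conc_a <= 0).any() or (self.conc_b <= 0).any():
            raise ValueError("concentrations must be strictly positive")
        if self.growth_combo.shape != (len(self.conc_a), len(self.conc_b)):
            raise ValueError(
                f"growth_combo shape {self.growth_combo.shape} does not match "
                f"grid {len(self.conc_a)}x{len(self.conc_b)}"
            )
        if np.isnan(self.growth_a).any() or np.isnan(self.growth_b).any():
            missing_a = [c for c, g in zip(self.conc_a, self.growth_a) if math.isnan(g)]
            missing_b = [c for c, g in zip(self.conc_b, self.growth_b) if math.isnan(g)]
            raise ValueError(
                f"missing single-agent growth for ({self.drug_a},{self.drug_b},"
                f"{self.cell_line}) at concentrations a={missing_a} b={missing_b}"
            )


@dataclass(frozen=True)
class SynergyRecord:
    """One ComboScore determination for a drug pair on a cell line."""

    drug_a: str
    drug_b: str
    cell_line: str
    center: str
    combo_score: float
    test_date: str = ""

    def __post_init__(self) -> None:
        if self.drug_a == self.drug_b:
            raise ValueError(f"self-combination {self.drug_a!r}")
        if not math.isfinite(self.combo_score):
            raise ValueError("combo_score must be finite")


@dataclass(frozen=True)
class SingleAgentRecord:
    """One single-agent percent-growth measurement (for replicate analysis)."""

    center: str
    drug: str
    conc: float
    cell_line: str
    test_date: str
    growth: float


def truncate_growth(y: float | np.ndarray) -> float | np.ndarray:
    """Clip percent growth into [−100, 100]."""
    return np.clip(y, -100.0, 100.0)


def bliss_expected(y_a: float, y_b: float) -> float:
    """Expected percent growth of a non-interacting pair.

    The product rule ``y_a*y_b/100`` applies when both agents leave growth
    positive; if either already drives growth to zero or below, the
    stronger agent's effect is the expectation (min branch).
    """
    if y_a > 0 and y_b > 0:
        return y_a * y_b / 100.0
    return min(y_a, y_b)


def combo_score(grid: DoseResponseGrid) -> float:
    """ComboScore: summed (Bliss-expected − observed) growth over the grid."""
    ga = truncate_growth(grid.growth_a)
    gb = truncate_growth(grid.growth_b)
    combo = truncate_growth(grid.growth_combo)
    score = 0.0
    for i in range(len(ga)):
        for j in range(len(gb)):
            score += bliss_expected(ga[i], gb[j]) - combo[i, j]
    return score


def grid_record(grid: DoseResponseGrid) -> SynergyRecord:
    """Score a grid into a SynergyRecord."""
    return SynergyRecord(
        drug_a=grid.drug_a,
        drug_b=grid.drug_b,
        cell_line=grid.cell_line,
        center=grid.center,
        combo_score=combo_score(grid),
        test_date=grid.test_date,
    )


def validate_center(code: str, allow_unknown: bool = False) -> str:
    code = str(code).strip()
    if code not in KNOWN_CENTERS and not allow_unknown:
        raise ValueError(
            f"unknown screening center {code!r}; expected one of {KNOWN_CENTERS} "
            "(pass allow_unknown=True to accept)"
        )
    return code


def write_combo_growth_csv(
    grids: list[DoseResponseGrid],
    singles: list[SingleAgentRecord],
    path_or_buf,
) -> None:
    """Write grids and single-agent records in the ComboDrugGrowth dialect."""
    rows = []
    for g in grids:
        for i, ca in enumerate(g.conc_a):
            for j, cb in enumerate(g.conc_b):
                rows.append(
                    {
                        "SCREENER": g.center,
                        "TESTDATE": g.test_date,
                        "CELLNAME": g.cell_line,
                        "NSC1": g.drug_a,
                        "CONC1": ca,
                        "NSC2": g.drug_b,
                        "CONC2": cb,
                        "PERCENTGROWTH": g.growth_combo[i, j],
                    }
                )
        # the grid's own single-agent anchor measurements
        for ca, ga in zip(g.conc_a, g.growth_a):
            rows.append(
                {
                    "SCREENER": g.center,
                    "TESTDATE": g.test_date,
                    "CELLNAME": g.cell_line,
                    "NSC1": g.drug_a,
                    "CONC1": ca,
                    "NSC2": "",
                    "CONC2": "",
                    "PERCENTGROWTH": ga,
                }
            )
        for cb, gb in zip(g.conc_b, g.growth_b):
            rows.append(
                {
                    "SCREENER": g.center,
                    "TESTDATE": g.test_date,
                    "CELLNAME": g.cell_line,
                    "NSC1": g.drug_b,
                    "CONC1": cb,
                    "NSC2": "",
                    "CONC2": "",
                    "PERCENTGROWTH": gb,
                }
            )
    for s in singles:
        rows.append(
            {
                "SCREENER": s.center,
                "TESTDATE": s.test_date,
                "CELLNAME": s.cell_line,
                "NSC1": s.drug,
                "CONC1": s.conc,
                "NSC2": "",
                "CONC2": "",
                "PERCENTGROWTH": s.growth,
            }
        )
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path_or_buf, index=False)


def read_combo_growth_csv(
    path_or_buf, allow_unknown_centers: bool = False
) -> tuple[list[DoseResponseGrid], list[SynergyRecord], list[SingleAgentRecord]]:
    """Read a ComboDrugGrowth CSV into grids, scored records and singles.

    Combination rows are assembled into dose–response grids keyed by
    (center, drug A, drug B, cell line, test date); single-agent rows are
    kept separately for the replicate-variability analysis and also anchor
    the grids' single-agent growth vectors.  Malformed rows are logged and
    skipped; a missing mandatory column raises.
    """
    df = pd.read_csv(path_or_buf, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory columns: {missing}")

    singles: list[SingleAgentRecord] = []
    combo_cells: dict[tuple, dict[tuple[float, float], float]] = {}
    single_lookup: dict[tuple, dict[float, list[float]]] = {}
    n_skipped = 0
    for row in df.itertuples(index=False):
        try:
            center = validate_center(row.SCREENER, allow_unknown_centers)
            growth = float(row.PERCENTGROWTH)
            conc1 = float(row.CONC1)
            nsc2 = str(row.NSC2).strip()
            if nsc2:
                conc2 = float(row.CONC2)
                key = (center, str(row.NSC1), nsc2, str(row.CELLNAME), str(row.TESTDATE))
                combo_cells.setdefault(key, {})[(conc1, conc2)] = growth
            else:
                rec = SingleAgentRecord(
                    center=center,
                    drug=str(row.NSC1),
                    conc=conc1,
                    cell_line=str(row.CELLNAME),
                    test_date=str(row.TESTDATE),
                    growth=growth,
                )
                singles.append(rec)
                skey = (center, rec.drug, rec.cell_line, rec.test_date)
                single_lookup.setdefault(skey, {}).setdefault(conc1, []).append(growth)
        except (ValueError, TypeError) as exc:
            n_skipped += 1
            logger.warning("skipping malformed row: %s (%s)", tuple(row), exc)
    if n_skipped:
        logger.info("skipped %d malformed rows", n_skipped)

    grids: list[DoseResponseGrid] = []
    records: list[SynergyRecord] = []
    for (center, a, b, cell, date), cells in sorted(combo_cells.items()):
        conc_a = sorted({ca for ca, _ in cells})
        conc_b = sorted({cb for _, cb in cells})
        mat = np.full((len(conc_a), len(conc_b)), np.nan)
        for (ca, cb), g in cells.items():
            mat[conc_a.index(ca), conc_b.index(cb)] = g
        if np.isnan(mat).any():
            logger.warning(
                "incomplete grid for (%s,%s,%s,%s,%s); skipped", center, a, b, cell, date
            )
            continue

        def agent_growth(drug: str, concs: list[float]) -> list[float] | None:
            by_conc = single_lookup.get((center, drug, cell, date), {})
            out = []
            for c in concs:
                vals = by_conc.get(c)
                if not vals:
                    return None
                out.append(float(np.mean(vals)))
            return out

        ga = agent_growth(a, conc_a)
        gb = agent_growth(b, conc_b)
        if ga is None or gb is None:
            logger.warning(
                "no single-agent anchor for grid (%s,%s,%s,%s,%s); skipped",
                center, a, b, cell, date,
            )
            continue
        grid = DoseResponseGrid(
            drug_a=a, drug_b=b, cell_line=cell, center=center,
            conc_a=np.array(conc_a), conc_b=np.array(conc_b),
            growth_a=np.array(ga), growth_b=np.array(gb),
            growth_combo=mat, test_date=date,
        )
        grids.append(grid)
        records.append(grid_record(grid))
    return grids, records, singles


def pair_key(drug_a: str, drug_b: str) -> tuple[str, str]:
    """Order-independent pair key, stored lexicographically."""
    return (drug_a, drug_b) if drug_a <= drug_b else (drug_b, drug_a)


def aggregate_labels(
    records: list[SynergyRecord], policy: str = "mean"
) -> dict[tuple[str, str, str, str], float]:
    """Collapse duplicate determinations of one (pair, cell line, center).

    ``policy`` is one of mean / median / first; the pair key is unordered.
    Returns {(drug_lo, drug_hi, cell_line, center): combo_score}.
    """
    if not records:
        raise ValueError("no records to aggregate")
    if policy not in ("mean", "median", "first"):
        raise ValueError(f"unknown aggregation policy {policy!r}")
    groups: dict[tuple, list[float]] = {}
    for r in records:
        a, b = pair_key(r.drug_a, r.drug_b)
        groups.setdefault((a, b, r.cell_line, r.center), []).append(r.combo_score)
    out = {}
    for key, vals in groups.items():
        if policy == "mean":
            out[key] = float(np.mean(vals))
        elif policy == "median":
            out[key] = float(np.median(vals))
        else:
            out[key] = vals[0]
    return out


def matrix_completeness(n_drugs: int, n_cell_lines: int, n_measured: int) -> float:
    """Measured fraction of the (pairs × cell lines) matrix, as a percentage.

    Reported to 2 decimals, e.g. the full NCI-ALMANAC panel (104 drugs,
    60 cell lines, 293,565 tuples) gives 91.35.
    """
    total = math.comb(n_drugs, 2) * n_cell_lines
    if n_measured > total:
        raise ValueError(f"n_measured {n_measured} exceeds matrix size {total}")
    return round(100.0 * n_measured / total, 2)


def labels_to_tsv(labels: dict[tuple[str, str, str, str], float]) -> str:
    """Serialize aggregated labels to the internal canonical TSV."""
    buf = io.StringIO()
    buf.write("drug_a\tdrug_b\tcell_line\tcenter\tcombo_score\n")
    for (a, b, cell, center), score in sorted(labels.items()):
        buf.write(f"{a}\t{b}\t{cell}\t{center}\t{score!r}\n")
    return buf.getvalue()
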