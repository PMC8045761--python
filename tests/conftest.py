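"""Shared fixtures: printed worked-example rows and small matrix builders."""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from polysel.io import (
    Condition,
    DesignCell,
    Fraction,
    Genotype,
    SampleMeta,
    SignalMatrix,
)

# Published worked-example rows: cold-regulated genes whose wild-type cold
# response vanishes in the mutant. Columns: gene, WT control mean, WT cold
# mean, printed WT fold, mutant control mean, mutant cold mean, printed
# mutant fold. Signed-fold convention: decreases as -(ref/alt).
# (One mutant control value is printed with a spurious minus sign in the
# source table; the value here is the positive signal consistent with the
# printed fold.)
COLD_DOWN_TOTAL_ROWS = [
    ("AT2G35500", 59.44, 36.24, -1.64, 54.41, 46.25, -1.18),
    ("AT1G48520", 50.43, 33.22, -1.52, 48.82, 38.20, -1.28),
    ("AT1G05010", 263.96, 155.29, -1.70, 245.05, 168.53, -1.45),
    ("AT5G52100", 38.08, 21.90, -1.74, 37.64, 25.78, -1.46),
    ("AT3G61440", 307.46, 177.60, -1.73, 291.31, 208.08, -1.40),
    ("AT3G27670", 7.04, 4.32, -1.63, 5.70, 4.44, -1.28),
    ("AT4G24660", 11.93, 7.44, -1.60, 16.07, 13.14, -1.22),
    ("AT2G41720", 18.60, 11.66, -1.59, 17.28, 13.98, -1.24),
    ("AT1G69770", 18.27, 11.71, -1.56, 15.97, 12.70, -1.26),
    ("AT5G18700", 6.56, 4.22, -1.56, 6.43, 5.06, -1.27),
    ("AT1G32200", 42.48, 23.69, -1.79, 36.16, 29.22, -1.24),
    ("AT1G23080", 68.25, 40.46, -1.69, 61.88, 49.27, -1.26),
]

# Additional printed (WT control, WT cold, fold) triples: cold-up total RNA,
# cold-down polysomal, cold-up polysomal.
COLD_UP_TOTAL_FOLDS = [
    ("AT2G40140", 31.55, 52.88, 1.68),
    ("AT5G59820", 11.83, 29.44, 2.49),
    ("AT3G05890", 223.74, 354.57, 1.58),
    ("AT5G10140", 2.70, 4.19, 1.55),
    ("AT4G25480", 8.95, 14.57, 1.63),
    ("AT4G25470", 17.27, 39.97, 2.31),
    ("AT4G02520", 225.38, 353.50, 1.57),
    ("AT2G30250", 12.20, 22.18, 1.82),
    ("AT1G76180", 709.28, 1270.5, 1.79),
    ("AT1G69270", 7.57, 11.76, 1.55),
    ("AT5G20230", 57.45, 110.29, 1.92),
    ("AT4G23600", 45.26, 77.25, 1.71),
    ("AT1G76930", 71.36, 166.58, 2.33),
    ("AT4G22880", 2.80, 7.66, 2.73),
    ("AT5G59720", 9.18, 17.51, 1.91),
    ("AT3G59220", 15.57, 25.18, 1.62),
]

COLD_DOWN_POLY_FOLDS = [
    ("AT1G11680", 8.10, 4.57, -1.77),
    ("AT1G13980", 8.16, 4.23, -1.93),
    ("AT1G14610", 23.82, 11.85, -2.01),
    ("AT1G36160", 16.81, 9.17, -1.83),
    ("AT1G69040", 25.35, 14.05, -1.80),
    ("AT1G74030", 28.10, 14.82, -1.90),
    ("AT1G80490", 10.83, 5.04, -2.15),
    ("AT3G48110", 12.10, 5.46, -2.22),
    ("AT3G53700", 9.80, 5.30, -1.85),
    ("AT3G62680", 11.04, 5.90, -1.87),
    ("AT4G04890", 18.75, 10.51, -1.78),
    ("AT4G38600", 15.45, 8.54, -1.81),
    ("AT5G23940", 7.22, 3.30, -2.18),
    ("AT5G26742", 94.75, 52.11, -1.82),
    ("AT5G37510", 49.08, 30.22, -1.62),
    ("AT5G52920", 58.21, 34.67, -1.68),
    ("AT5G65930", 8.92, 4.12, -2.17),
]

COLD_UP_POLY_FOLDS = [
    ("AT3G61190", 2.54, 8.35, 3.29),
    ("AT1G72450", 16.30, 27.81, 1.71),
    ("AT5G43580", 22.69, 41.33, 1.82),
    ("AT1G01720", 11.12, 21.17, 1.90),
    ("AT4G12030", 18.72, 30.87, 1.65),
    ("AT1G27730", 16.43, 31.61, 1.92),
    ("AT3G51660", 37.34, 102.22, 2.74),
]


def make_cell(genotype="WT", condition="CK", fraction="TOTAL") -> DesignCell:
    return DesignCell(Genotype(genotype), Condition(condition), Fraction(fraction))


def matrix_from_cell_means(
    genes: list[str],
    cell_means: dict[DesignCell, np.ndarray],
    n_reps: int = 2,
) -> SignalMatrix:
    """Noise-free matrix: each design cell's replicates duplicate the mean."""
    samples = []
    columns = []
    for cell, means in cell_means.items():
        means = np.asarray(means, dtype=float)
        for r in range(1, n_reps + 1):
            samples.append(
                SampleMeta(
                    sample_id=f"{cell}_{r}",
                    genotype=cell.genotype,
                    condition=cell.condition,
                    fraction=cell.fraction,
                    replicate=r,
                )
            )
            columns.append(means)
    return SignalMatrix(genes=genes, samples=samples, values=np.column_stack(columns))


@pytest.fixture
def table1_matrix() -> SignalMatrix:
    """Noise-free 12-gene matrix over the four total-RNA design cells."""
    genes = [row[0] for row in COLD_DOWN_TOTAL_ROWS]
    arr = np.array([row[1:7:1] for row in COLD_DOWN_TOTAL_ROWS])
    return matrix_from_cell_means(
        genes,
        {
            make_cell("WT", "CK", "TOTAL"): arr[:, 0],
            make_cell("WT", "COLD", "TOTAL"): arr[:, 1],
            make_cell("MUT", "CK", "TOTAL"): arr[:, 3],
            make_cell("MUT", "COLD", "TOTAL"): arr[:, 4],
        },
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
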