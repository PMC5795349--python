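"""Greenhouse experimental design: the 10x16 pot grid and its randomization.

The experiment grows 156 maize plants (32 inbred genotypes, ZL1-ZL32) plus
4 empty control pots on a 10-row by 16-column greenhouse grid.  Each
sequential pair of rows forms one complete replicate; within a replicate,
genotypes are blocked into half-rows of 8 pots, and only the order *within*
a block is randomized between replicates.  Genotype ZL22 is present in a
single replicate only; the other four replicates carry an empty pot in its
place, which is why the design has exactly 4 empties and 156 plants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_ROWS = 10
N_COLS = 16
N_REPLICATES = 5
BLOCK_SIZE = 8
N_GENOTYPES = 32
EMPTY = "EMPTY"

# Published greenhouse layout, genotype number per pot, 0 = empty control pot.
# Rows are greenhouse rows (pairs form replicates), columns are pot positions.
LAYOUT = np.array(
    [
        [9, 7, 3, 10, 23, 25, 26, 19, 13, 5, 29, 21, 2, 4, 18, 20],
        [11, 16, 1, 32, 17, 27, 6, 22, 24, 31, 14, 30, 15, 28, 8, 12],
        [29, 31, 15, 13, 1, 17, 25, 9, 21, 30, 3, 5, 0, 19, 14, 6],
        [12, 23, 32, 16, 7, 28, 2, 18, 10, 11, 8, 26, 27, 4, 20, 24],
        [25, 9, 21, 27, 28, 12, 5, 11, 15, 6, 0, 7, 4, 23, 31, 20],
        [19, 32, 29, 24, 16, 13, 3, 8, 17, 14, 18, 30, 10, 26, 1, 2],
        [8, 1, 17, 23, 21, 5, 7, 24, 27, 18, 3, 11, 31, 15, 19, 2],
        [25, 30, 4, 9, 16, 32, 14, 20, 0, 10, 6, 29, 28, 12, 26, 13],
        [15, 10, 5, 32, 31, 21, 16, 26, 2, 18, 9, 25, 6, 8, 24, 0],
        [29, 13, 23, 14, 27, 7, 11, 30, 12, 1, 28, 4, 3, 20, 17, 19],
    ],
    dtype=int,
)


def genotype_label(num: int) -> str:
    """Genotype id string for a 1-based genotype number ('ZL7'); 0 -> EMPTY."""
    return EMPTY if num == 0 else f"ZL{num}"


def plant_label(row: int, col: int, num: int) -> str:
    """Plant id in the released-dataset style, e.g. '023-7' (pot number-genotype)."""
    pot = (row - 1) * N_COLS + col
    return f"{pot:03d}-{num}"


@dataclass(frozen=True)
class PotAssignment:
    row: int          # greenhouse row, 1-10
    col: int          # pot position within row, 1-16
    genotype: str     # 'ZL1'..'ZL32' or 'EMPTY'
    replicate: int    # 1-5; replicate r occupies rows 2r-1 and 2r
    block: int        # 1-4 within replicate (half-rows of 8)


@dataclass(frozen=True)
class ExperimentDesign:
    """Immutable pot-grid design; `table` has one record per grid cell."""

    grid: np.ndarray = field(repr=False)  # (10, 16) genotype numbers, 0=empty

    def __post_init__(self) -> None:
        if self.grid.shape != (N_ROWS, N_COLS):
            raise ValueError(f"design grid must be {N_ROWS}x{N_COLS}")
        validate_layout(self.grid)

    @property
    def table(self) -> pd.DataFrame:
        rows = []
        for i in range(N_ROWS):
            for j in range(N_COLS):
                num = int(self.grid[i, j])
                rows.append(
                    {
                        "row": i + 1,
                        "col": j + 1,
                        "genotype": genotype_label(num),
                        "replicate": i // 2 + 1,
                        "block": (i % 2) * 2 + j // BLOCK_SIZE + 1,
                        "plant": plant_label(i + 1, j + 1, num),
                        "occupied": num > 0,
                    }
                )
        return pd.DataFrame(rows)

    @property
    def occupied(self) -> pd.DataFrame:
        """Records for the 156 planted pots only."""
        t = self.table
        return t[t["occupied"]].reset_index(drop=True)

    def genotype_at(self, row: int, col: int) -> str:
        return genotype_label(int(self.grid[row - 1, col - 1]))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @staticmethod
    def from_csv(path) -> "ExperimentDesign":
        t = pd.read_csv(path)
        grid = np.zeros((N_ROWS, N_COLS), dtype=int)
        for rec in t.itertuples():
            g = rec.genotype
            grid[rec.row - 1, rec.col - 1] = 0 if g == EMPTY else int(g[2:])
        return ExperimentDesign(grid)


def validate_layout(grid: np.ndarray) -> None:
    """Check the design invariants; raise ValueError on violation."""
    occ = int((grid > 0).sum())
    if occ != 156 or int((grid == 0).sum()) != 4:
        raise ValueError(f"expected 156 occupied + 4 empty pots, got {occ} occupied")
    nums = grid[grid > 0]
    if len(np.unique(nums)) != N_GENOTYPES:
        raise ValueError("expected 32 distinct genotypes")
    if int((nums == 22).sum()) != 1:
        raise ValueError("ZL22 must appear exactly once")
    for r in range(N_REPLICATES):
        pair = grid[2 * r : 2 * r + 2].ravel()
        pair = pair[pair > 0]
        if np.any(np.bincount(pair) > 1):
            raise ValueError(f"genotype repeated within replicate {r + 1}")


def paper_design() -> ExperimentDesign:
    """The design exactly as printed in the released layout table."""
    return ExperimentDesign(LAYOUT.copy())


def generate_design(seed: int) -> ExperimentDesign:
    """Randomized design: fixed genotype-to-block composition, order shuffled.

    The genotype content of each half-row block is held fixed at the published
    layout; a seeded permutation is applied within every block, mirroring how
    the experiment randomized pot order within blocks between replicates.
    Identical seeds give identical designs.
    """
    rng = np.random.default_rng(seed)
    grid = LAYOUT.copy()
    for i in range(N_ROWS):
        for b in range(N_COLS // BLOCK_SIZE):
            sl = slice(b * BLOCK_SIZE, (b + 1) * BLOCK_SIZE)
            grid[i, sl] = rng.permutation(grid[i, sl])
    return ExperimentDesign(grid)
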