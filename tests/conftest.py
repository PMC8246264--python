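"""Shared fixtures: tiny in-memory file fixtures are built programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from splicekit.io_formats import TankGeometry, TrajectoryFile

RMATS_SE_HEADER = (
    "ID\tGeneID\tgeneSymbol\tchr\tstrand\texonStart_0base\texonEnd\t"
    "upstreamES\tupstreamEE\tdownstreamES\tdownstreamEE\t"
    "IncLevel1\tIncLevel2\tPValue\tFDR\tIncLevelDifference"
)


def make_rmats_se(rows: list[dict]) -> str:
    """Render rMATS SE rows (dicts with inc1, inc2, pvalue, fdr, ...) to TSV."""
    lines = [RMATS_SE_HEADER]
    for i, row in enumerate(rows):
        start = row.get("start", 1000 + 2000 * i)
        inc1 = ",".join(str(v) for v in row["inc1"])
        inc2 = ",".join(str(v) for v in row["inc2"])
        dpsi = row.get(
            "dpsi",
            np.mean([v for v in row["inc1"] if not np.isnan(v)])
            - np.mean([v for v in row["inc2"] if not np.isnan(v)]),
        )
        lines.append(
            f"{row.get('id', i)}\t{row.get('gene', f'g{i}')}\tsym\t"
            f"{row.get('chrom', 'chr1')}\t{row.get('strand', '+')}\t"
            f"{start + 500}\t{start + 650}\t{start}\t{start + 150}\t"
            f"{start + 1150}\t{start + 1300}\t"
            f"{inc1}\t{inc2}\t{row.get('pvalue', 0.5)}\t{row.get('fdr', 0.5)}\t{dpsi}"
        )
    return "\n".join(lines) + "\n"


@pytest.fixture
def rmats_se_file(tmp_path):
    def write(rows: list[dict], name: str = "SE.MATS.JC.txt"):
        path = tmp_path / name
        path.write_text(make_rmats_se(rows))
        return path

    return write


def make_trajectory(
    positions: np.ndarray, fps: float = 10.0, frames: np.ndarray | None = None
) -> TrajectoryFile:
    """Trajectory from an (n, 2) position array in cm."""
    positions = np.asarray(positions, dtype=float)
    return TrajectoryFile(
        frames=frames if frames is not None else np.arange(len(positions)),
        x_cm=positions[:, 0],
        y_cm=positions[:, 1],
        fps=fps,
        tank=TankGeometry(),
    )
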