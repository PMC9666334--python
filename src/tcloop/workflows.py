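"""High-level drivers that tie the analysis modules into run artifacts."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from .basins import map_basins_2d
from .bifurcation import find_threshold, sweep
from .kinetics import ModelParams

__all__ = ["reproduce_figure2"]

log = logging.getLogger(__name__)

#: Float formatting for all CSV/JSON artifacts: 10 significant digits.
FLOAT_FMT = "%.10g"


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, default=float))


def reproduce_figure2(
    outdir,
    params: ModelParams | None = None,
    a_step: float = 0.001,
    basin_a_values=(1.0, 0.26, 0.15),
    T_init: float = 80.0,
    png: bool = False,
) -> dict:
    """Bifurcation diagram plus representative basin maps, written to disk.

    Sweeps the equilibrium branches over a in [0, 0.5] (the range where
    the branch structure changes), locates the fold a-hat, and maps
    basins of attraction at a monostable exemplar (a=1) and two bistable
    values just below the fold, all with T(0) = 80 Hz — the TRN ceiling,
    where the baseline basin is at its widest.  Returns the paths and
    headline numbers; writes CSV tables, a JSON summary and (optionally)
    PNG renderings.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if params is None:
        params = ModelParams()
    artifacts: dict = {"outdir": str(outdir)}

    t0 = time.perf_counter()
    fold = find_threshold(params)
    artifacts["a_hat"] = fold.a_hat
    _write_json(outdir / "a_hat.json",
                {"a_hat": fold.a_hat, "status": fold.status})
    log.info("fold search: a_hat=%s (%s) in %.2f s", fold.a_hat, fold.status,
             time.perf_counter() - t0)

    t0 = time.perf_counter()
    a_grid = np.arange(0.0, 0.5 + 0.5 * a_step, a_step)
    diagram = sweep(params, a_grid)
    df = diagram.to_dataframe()
    branch_path = outdir / "bifurcation_branches.csv"
    df.to_csv(branch_path, index=False, float_format=FLOAT_FMT)
    artifacts["branches_csv"] = str(branch_path)
    log.info("branch sweep: %d grid points, %d rows in %.2f s",
             len(a_grid), len(df), time.perf_counter() - t0)

    fractions = {}
    for a in basin_a_values:
        t0 = time.perf_counter()
        grid = map_basins_2d(params.with_a(a), T_init=T_init)
        tag = f"a{a:g}".replace(".", "p")
        csv_path = outdir / f"basins_{tag}.csv"
        grid.to_dataframe().to_csv(csv_path, index=False,
                                   float_format=FLOAT_FMT)
        fractions[str(a)] = grid.area_fraction
        log.info("basins at a=%g: fractions %s in %.2f s", a,
                 grid.area_fraction, time.perf_counter() - t0)
        if png:
            from .plotting import plot_basin_grid

            plot_basin_grid(grid, outdir / f"basins_{tag}.png")
    _write_json(outdir / "basin_fractions.json", fractions)
    artifacts["basin_fractions"] = fractions

    if png:
        from .plotting import plot_bifurcation

        plot_bifurcation(diagram, outdir / "bifurcation.png")
    return artifacts
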