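"""End-to-end driver: simulate -> reconstruct -> turnover -> phenotype.

``run_pipeline`` executes the full analysis on a scenario and writes a small
artifact directory:

* ``cohort.csv``        -- simulated ontogeny cohort (counts only)
* ``adult_cohort.csv``  -- adult-pulse persistence cohort
* ``composition.csv``   -- per-tissue (and per-subset) generation-week shares
* ``waffle.txt``        -- 10x10 text waffles of the compositions
* ``decay.csv``         -- exponential-with-plateau label-decay fits
* ``report.csv``        -- tagged-vs-untagged marker statistics
* ``run.log``           -- resolved configuration and seed

Outputs are byte-identical for identical configuration and seed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .composition import PoolCompositionModel, waffle_text
from .exceptions import TregmapError
from .io import write_cohort
from .phenotype import marker_columns, marker_report
from .scenario import Scenario, load_scenario, simulate_cohort
from .turnover import LabelDecayModel

logger = logging.getLogger(__name__)


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""

    class _Ctx:
        def __enter__(self):
            logger.info("pipeline stage: %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, TregmapError):
                raise type(exc)(f"[stage {name}] {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(
    scenario: Scenario | str | Path | None = None,
    outdir: str | Path = "tregmap-run",
    seed: int | None = None,
    bootstrap: int = 1000,
) -> dict[str, Path]:
    """Run the whole analysis on a scenario; returns the artifact paths."""
    if scenario is None or isinstance(scenario, (str, Path)):
        scenario = load_scenario(scenario)
    seed = scenario.seed if seed is None else int(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(seed).spawn(3)
    artifacts: dict[str, Path] = {}

    log_lines = [
        f"scenario: {scenario.name} ({scenario.source})",
        f"seed: {seed}",
        f"bootstrap: {bootstrap}",
        f"tissues: {', '.join(scenario.tissues)}",
    ]

    with _stage("simulate"):
        cohort = simulate_cohort(
            scenario, "ontogeny", rng=np.random.default_rng(seeds[0])
        )
        adult = simulate_cohort(
            scenario, "adult_pulse", rng=np.random.default_rng(seeds[1])
        )
        artifacts["cohort"] = outdir / "cohort.csv"
        write_cohort(cohort, artifacts["cohort"])
        artifacts["adult_cohort"] = outdir / "adult_cohort.csv"
        write_cohort(adult, artifacts["adult_cohort"])
        log_lines.append(f"ontogeny cohort: {len(cohort)} records")
        log_lines.append(f"adult-pulse cohort: {len(adult)} records")

    with _stage("reconstruct"):
        frames = []
        waffles = []
        seed_rng = np.random.default_rng(seeds[2])
        for tissue in scenario.tissues:
            for subset in [None] + scenario.subsets(tissue):
                model = PoolCompositionModel(
                    cohort, tissue, scenario.efficiency, subset=subset
                )
                res = model.fit(bootstrap=bootstrap, seed=int(seed_rng.integers(2**31)))
                frames.append(res.to_frame())
                label = tissue if subset is None else f"{tissue}/{subset}"
                labels = [f"w{w}" for w in res.pulse_weeks] + ["later"]
                waffles.append(f"== {label} ==\n{waffle_text(res.waffle(), labels)}")
        composition = pd.concat(frames, ignore_index=True)
        artifacts["composition"] = outdir / "composition.csv"
        composition.to_csv(artifacts["composition"], index=False)
        artifacts["waffle"] = outdir / "waffle.txt"
        artifacts["waffle"].write_text("\n\n".join(waffles) + "\n")

    with _stage("turnover"):
        fits = []
        for tissue in scenario.tissues:
            model = LabelDecayModel.from_cohort(adult, tissue)
            fits.append(model.fit(free_plateau=True).to_frame())
        decay = pd.concat(fits, ignore_index=True)
        artifacts["decay"] = outdir / "decay.csv"
        decay.to_csv(artifacts["decay"], index=False)

    with _stage("phenotype"):
        reports = []
        for tissue in scenario.tissues:
            if not scenario.markers(tissue):
                continue
            reports.append(marker_report(cohort, tissue, list(scenario.markers(tissue))))
        if reports:
            report = pd.concat(reports, ignore_index=True)
            artifacts["report"] = outdir / "report.csv"
            report.to_csv(artifacts["report"], index=False)
            log_lines.append(f"markers analysed: {sorted(set(marker_columns(cohort)))}")

    artifacts["log"] = outdir / "run.log"
    artifacts["log"].write_text("\n".join(log_lines) + "\n")
    logger.info("pipeline artifacts written to %s", outdir)
    return artifacts
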