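"""Campaign runner: parameter sweeps with resumable on-disk layout.

A campaign is a base condition plus sweep axes (lists of values for any
parameter, including box height).  Each (condition, run) gets a unique
derived seed; completed runs are tracked in a manifest so an
interrupted campaign resumes where it stopped.

Layout::

    outdir/
      manifest.json
      <condition>/run-00.csv ...
      <condition>/summary.json
      campaign.csv            # K_eq vs condition
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .engine import Trajectory, derive_run_seed, run_simulation
from .io import read_timeseries_csv, write_summary_json, write_timeseries_csv
from .observables import quasi_equilibrium_summary
from .params import ParameterSet


@dataclass
class Campaign:
    base: ParameterSet
    axes: dict = field(default_factory=dict)  # field name -> list of values
    n_runs: int | None = None

    def conditions(self) -> list[tuple[dict, ParameterSet]]:
        """All concrete conditions (cartesian product over the axes)."""
        if not self.axes:
            return [({}, self.base)]
        names = list(self.axes)
        out = []
        for combo in itertools.product(*(self.axes[n] for n in names)):
            override = dict(zip(names, combo))
            out.append((override, self.base.with_(**override)))
        return out


def _condition_tag(override: dict) -> str:
    if not override:
        return "base"
    return "_".join(f"{k}={v}" for k, v in sorted(override.items()))


def run_campaign(campaign: Campaign, outdir) -> pd.DataFrame:
    """Execute every (condition, run), skipping runs recorded in the
    manifest; failures are isolated per run and marked in the summary.

    Returns the campaign-level table of K_eq per condition.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}

    n_runs = campaign.n_runs or campaign.base.n_runs
    rows = []
    for ci, (override, params) in enumerate(campaign.conditions()):
        tag = _condition_tag(override)
        cdir = outdir / tag
        cdir.mkdir(exist_ok=True)
        runs: list[Trajectory] = []
        failures = 0
        for k in range(n_runs):
            run_key = f"{tag}/run-{k:02d}"
            csv_path = cdir / f"run-{k:02d}.csv"
            seed = derive_run_seed(params.seed + 1000 * ci, k)
            if manifest.get(run_key) == "done" and csv_path.exists():
                data = read_timeseries_csv(csv_path)
                tr = Trajectory(
                    data=data,
                    params=params,
                    seed=seed,
                    n_monomer0=int(data.n_monomer.iloc[0] + 2 * data.n_dimer.iloc[0]),
                    n_inert=0,
                )
                runs.append(tr)
                continue
            try:
                tr = run_simulation(params, seed=seed)
            except Exception as exc:  # isolate per-run failures
                failures += 1
                manifest[run_key] = f"failed: {exc}"
                continue
            write_timeseries_csv(csv_path, tr.data)
            manifest[run_key] = "done"
            manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
            runs.append(tr)
        row = {**override, "condition": tag, "n_runs_done": len(runs), "failures": failures}
        if runs:
            est = quasi_equilibrium_summary(runs)
            write_summary_json(
                cdir / "summary.json",
                {
                    "condition": tag,
                    "k_eq_m3": est.k_eq_m3,
                    "mean_dimers": est.mean_dimers,
                    "std_dimers": est.std_dimers,
                    "n_runs": est.n_runs,
                    "sample_times_us": est.sample_times_us,
                    "seeds": [tr.seed for tr in runs],
                },
                params=params,
            )
            row.update(k_eq_m3=est.k_eq_m3, mean_dimers=est.mean_dimers)
        rows.append(row)
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "campaign.csv", index=False)
    return table
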