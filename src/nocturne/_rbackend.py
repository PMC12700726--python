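"""Subprocess bridge to the R model engines (mgcv, lme4).

The GAM and GLMM stages are fitted by mgcv and lme4 through Rscript;
data and a JSON model description go to a temporary directory, the R
side writes a JSON result.  Batch mode (a ``replicate`` column in the
data) fits every replicate in a single R session, which is what keeps
the simulation studies fast.
"""

from __future__ import annotations

import json
import shutil
import subprocess
import tempfile
from importlib import resources
from pathlib import Path
from typing import Any

import pandas as pd

__all__ = ["run_r_json", "r_available"]


def r_available() -> bool:
    return shutil.which("Rscript") is not None


def _script_path(name: str) -> Path:
    ref = resources.files("nocturne").joinpath("r", name)
    with resources.as_file(ref) as p:
        return Path(p)


def run_r_json(script: str, data: pd.DataFrame, config: dict[str, Any]) -> Any:
    """Run a packaged R script on (data.csv, config.json) -> result.json."""
    if not r_available():
        raise RuntimeError(
            "Rscript not found on PATH; the GAM/GLMM stages need R with mgcv and lme4"
        )
    with tempfile.TemporaryDirectory(prefix="nocturne_r_") as tmp:
        tmpdir = Path(tmp)
        data.to_csv(tmpdir / "data.csv", index=False)
        (tmpdir / "config.json").write_text(json.dumps(config))
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(_script_path(script)), str(tmpdir)],
            capture_output=True,
            text=True,
        )
        result_file = tmpdir / "result.json"
        if proc.returncode != 0 or not result_file.exists():
            raise RuntimeError(
                f"R backend failed ({script}):\n{proc.stdout}\n{proc.stderr}"
            )
        return json.loads(result_file.read_text())
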