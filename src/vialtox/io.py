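"""CSV readers/writers and the run manifest.

All tables are plain CSV with header rows; concentrations are always
in uM.  Readers validate the columns each stage needs and return
pandas DataFrames; the manifest records input hashes, the echoed
configuration, and library versions for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import sys
from pathlib import Path

import pandas as pd

__all__ = [
    "read_morphology", "read_traces", "read_body_burden", "read_logkow",
    "read_de_table", "read_counts", "read_docking", "write_table",
    "write_manifest",
]


def _read(path, required, name):
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{name} table {path} missing columns: {missing}")
    return df


def read_morphology(path) -> pd.DataFrame:
    """Long per-embryo outcomes: chemical, conc_um, vial, endpoint, response."""
    return _read(path, ["chemical", "conc_um", "vial", "endpoint", "response"],
                 "morphology")


def read_traces(path) -> pd.DataFrame:
    """Tidy tracking export: plate, well, chemical, conc_um, excluded,
    t_start_s, movement."""
    return _read(path, ["plate", "well", "chemical", "conc_um", "excluded",
                        "t_start_s", "movement"], "trace")


def read_body_burden(path) -> pd.DataFrame:
    """Measured extract concentrations per pooled replicate."""
    return _read(path, ["chemical", "timepoint_hpf", "replicate",
                        "ng_per_mL"], "body-burden")


def read_logkow(path) -> pd.DataFrame:
    """Predicted logKow per chemical."""
    return _read(path, ["chemical", "logkow"], "logkow")


def read_de_table(path) -> pd.DataFrame:
    """Differential-expression results: gene, chemical, log2fc, padj."""
    return _read(path, ["gene", "chemical", "log2fc", "padj"], "DE")


def read_counts(path) -> pd.DataFrame:
    """Gene x sample counts matrix with genes in the first column."""
    return pd.read_csv(path, index_col=0)


def read_docking(path) -> pd.DataFrame:
    """Long docking energies: chemical, protein, pocket, method, energy."""
    return _read(path, ["chemical", "protein", "pocket", "method",
                        "energy_kcal_mol"], "docking")


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir, config: dict, inputs: dict, outputs: list) -> Path:
    """Machine-readable run manifest: config echo, input hashes, versions."""
    import numpy
    import scipy
    import statsmodels

    from . import __version__

    manifest = {
        "config": config,
        "inputs": {name: {"path": str(p), "sha256": _sha256(p)}
                   for name, p in inputs.items() if p and Path(p).exists()},
        "outputs": [str(p) for p in outputs],
        "versions": {
            "vialtox": __version__,
            "python": sys.version.split()[0],
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }
    path = Path(outdir) / "manifest.json"
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2))
    return path
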