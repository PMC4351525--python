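"""Shared file formats, run configuration and output provenance headers.

Canonical interchange formats:

* SMILES table — tab-separated ``drug_id<TAB>smiles``, no header.
* SDF — V2000/V3000 multi-molecule; 3D coordinates are used directly when
  present, bypassing conformer embedding.
* Similarity matrix — CSV with a drug_id header row and column, values at
  6 decimal places.
* Reference standard — long-format TSV (drug_id, ade_id) or a binary
  matrix CSV.
* Scores — long-format CSV (drug_id, ade_id, score, algorithm
  [, provenance_drug]).
* Signal table — TSV/CSV with header drug_id, ade_id, ebgm, t, p.

Every file written here starts with ``#`` comment lines carrying the tool
version, seed and configuration hash, so any output can be traced to the
run that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ade_predictor import InputError, ReferenceStandard, ScoreMatrix, SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "setup_logging",
    "read_smiles_table",
    "read_sdf",
    "write_similarity_matrix",
    "read_similarity_matrix",
    "read_reference_table",
    "write_scores",
    "read_scores",
    "read_signals",
    "write_json_report",
    "write_sites",
]


@dataclass
class RunConfig:
    """Run parameters shared across the pipeline stages."""

    seed: int = 0
    n_starts: int = 10
    n_confs: int = 50
    min_drugs_per_ade: int = 5
    train_fraction: float = 0.8
    ks: tuple[int, ...] = tuple(range(100, 1001, 100))
    overlap_model: str = "gaussian"  # or "hard_sphere"
    protonate: bool = True
    algorithm: str = "max"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ks"] = list(self.ks)
        return d

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        if "ks" in data:
            data["ks"] = tuple(int(k) for k in data["ks"])
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:12]

    def header_lines(self) -> list[str]:
        return [
            f"# pharmsim {__version__}",
            f"# seed: {self.seed}",
            f"# config: {self.config_hash()}",
        ]

    def echo(self, outdir: str | Path) -> Path:
        """Serialize the config into an output directory."""
        out = Path(outdir) / "config.yaml"
        out.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return out


def setup_logging(verbose: bool = False, logfile: str | Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        handlers=handlers,
        force=True,
    )


# --- molecules -------------------------------------------------------------


def read_smiles_table(path: str | Path) -> pd.DataFrame:
    """Read a ``drug_id<TAB>smiles`` file into a two-column DataFrame.

    Lines starting with ``#`` are skipped; ``#`` elsewhere is part of the
    SMILES (triple bonds), so pandas' comment handling cannot be used.
    """
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
            raise InputError(f"malformed SMILES table line {lineno} in {path}")
        rows.append((parts[0].strip(), parts[1].strip()))
    if not rows:
        raise InputError(f"empty SMILES table: {path}")
    return pd.DataFrame(rows, columns=["drug_id", "smiles"])


def read_sdf(path: str | Path) -> list:
    """Read an SDF into RDKit mols (3D coordinates preserved when present)."""
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    mols = []
    for i, mol in enumerate(supplier):
        if mol is None:
            logger.warning("skipping unreadable SDF record %d in %s", i, path)
            continue
        mols.append(mol)
    return mols


# --- matrices --------------------------------------------------------------


def _write_with_header(path: Path, body: str, config: RunConfig | None) -> None:
    header = "\n".join(config.header_lines()) + "\n" if config is not None else ""
    path.write_text(header + body)


def write_similarity_matrix(
    ma: SimilarityMatrix, path: str | Path, config: RunConfig | None = None
) -> None:
    df = pd.DataFrame(ma.S, index=ma.drugs, columns=ma.drugs)
    body = df.to_csv(float_format="%.6f", index_label="drug_id")
    _write_with_header(Path(path), body, config)


def read_similarity_matrix(path: str | Path) -> SimilarityMatrix:
    df = pd.read_csv(path, comment="#", index_col=0)
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise InputError(f"similarity matrix {path} is not square-labelled")
    return SimilarityMatrix(list(df.columns.astype(str)), df.to_numpy(dtype=float))


def read_reference_table(path: str | Path) -> pd.DataFrame:
    """Read a drug-ADE standard: long TSV/CSV or binary matrix CSV.

    A file whose header contains drug_id/ade_id columns (or a headerless
    two-column TSV) is treated as long format; otherwise it is parsed as a
    binary matrix with drug rows and ADE columns and melted to long form.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    cols = [c.strip().lower() for c in df.columns]
    if "drug_id" in cols and "ade_id" in cols:
        df.columns = cols
        return df[["drug_id", "ade_id"]]
    if len(df.columns) == 2 and not set(df.iloc[:, 1]).issubset({"0", "1"}):
        # headerless long table: first row was data
        out = pd.read_csv(path, sep=sep, comment="#", header=None,
                          names=["drug_id", "ade_id"], dtype=str)
        return out
    dense = pd.read_csv(path, sep=sep, comment="#", index_col=0)
    long = dense.stack().reset_index()
    long.columns = ["drug_id", "ade_id", "value"]
    long = long[long["value"].astype(float) > 0]
    return long[["drug_id", "ade_id"]].astype(str)


def write_scores(
    mc: ScoreMatrix, path: str | Path, config: RunConfig | None = None
) -> None:
    body = mc.to_long().to_csv(index=False, float_format="%.6f")
    _write_with_header(Path(path), body, config)


def read_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    required = {"drug_id", "ade_id", "score"}
    if not required.issubset(df.columns):
        raise InputError(f"score file {path} lacks columns {sorted(required)}")
    df["drug_id"] = df["drug_id"].astype(str)
    df["ade_id"] = df["ade_id"].astype(str)
    return df


def scores_to_matrix(df: pd.DataFrame) -> ScoreMatrix:
    """Reassemble a long score table into a dense ScoreMatrix."""
    pivot = df.pivot(index="drug_id", columns="ade_id", values="score")
    algorithm = str(df["algorithm"].iloc[0]) if "algorithm" in df.columns else "unknown"
    return ScoreMatrix(
        list(pivot.index), list(pivot.columns), pivot.to_numpy(dtype=float), algorithm
    )


def read_signals(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    rename = {"t_statistic": "t", "p_value": "p"}
    df = df.rename(columns=rename)
    return df


def write_json_report(report: dict, path: str | Path, config: RunConfig | None = None) -> None:
    payload = dict(report)
    if config is not None:
        payload["_provenance"] = {
            "tool": f"pharmsim {__version__}",
            "seed": config.seed,
            "config_hash": config.config_hash(),
        }
    Path(path).write_text(json.dumps(payload, indent=2, allow_nan=True))


def write_sites(site_sets, path: str | Path, config: RunConfig | None = None) -> None:
    """Dump pharmacophore sites as a flat table (drug_id, site_type, x, y, z)."""
    rows = [
        {"drug_id": ss.drug_id, "site_type": s.site_type,
         "x": s.center[0], "y": s.center[1], "z": s.center[2]}
        for ss in site_sets
        for s in ss.sites
    ]
    body = pd.DataFrame(rows, columns=["drug_id", "site_type", "x", "y", "z"]).to_csv(
        index=False, float_format="%.4f"
    )
    _write_with_header(Path(path), body, config)
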