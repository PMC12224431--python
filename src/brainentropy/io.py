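"""Table and image plumbing shared by the CLI and scripts.

All tables are TSV: tab-separated, header row, UTF-8, '.' decimal, NaN
written as "NA".  Floats use a fixed "%.10g" format so a rerun with the
same seed produces byte-identical files.  Node matrices are stored one scan
per file with columns named ``node_<id>``, indexed by a manifest table.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .prep import NodeTimeSeriesMatrix, ParcellationAtlas

__all__ = [
    "write_table",
    "read_table",
    "write_matrix",
    "read_matrix",
    "write_cohort_scans",
    "read_cohort_scans",
    "load_atlas",
    "save_atlas",
    "write_run_log",
    "read_config_file",
    "file_sha256",
]

FLOAT_FORMAT = "%.10g"


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep="NA",
              float_format=FLOAT_FORMAT, lineterminator="\n")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)


def write_matrix(mat: NodeTimeSeriesMatrix, path: str | Path) -> Path:
    df = pd.DataFrame(mat.values, columns=[f"node_{int(n)}" for n in mat.node_ids])
    return write_table(df, path)


def read_matrix(path: str | Path, subject_id: str = "", condition: str = "",
                session: str = "", normalized: bool = False) -> NodeTimeSeriesMatrix:
    df = read_table(path)
    node_ids = np.array([int(c.removeprefix("node_")) for c in df.columns], dtype=np.int64)
    return NodeTimeSeriesMatrix(values=df.to_numpy(dtype=np.float64), node_ids=node_ids,
                                subject_id=subject_id, condition=condition,
                                session=session, normalized=normalized)


def write_cohort_scans(matrices: list[NodeTimeSeriesMatrix], out_dir: str | Path) -> Path:
    """Write one TSV per scan plus a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    scans = out_dir / "scans"
    scans.mkdir(parents=True, exist_ok=True)
    rows = []
    for mat in matrices:
        name = f"{mat.subject_id}_{mat.condition}_{mat.session}.tsv"
        write_matrix(mat, scans / name)
        rows.append(dict(subject_id=mat.subject_id, condition=mat.condition,
                         session=mat.session, path=f"scans/{name}"))
    manifest = pd.DataFrame(rows, columns=["subject_id", "condition", "session", "path"])
    return write_table(manifest, out_dir / "manifest.tsv")


def read_cohort_scans(manifest_path: str | Path):
    """Yield NodeTimeSeriesMatrix objects listed in a manifest TSV."""
    manifest_path = Path(manifest_path)
    manifest = read_table(manifest_path)
    base = manifest_path.parent
    for rec in manifest.itertuples(index=False):
        yield read_matrix(base / rec.path, subject_id=str(rec.subject_id),
                          condition=str(rec.condition), session=str(rec.session))


def load_atlas(volume_path: str | Path, labels_path: str | Path) -> ParcellationAtlas:
    img = nib.load(str(volume_path))
    volume = np.asarray(img.dataobj)
    if not np.issubdtype(volume.dtype, np.integer):
        rounded = np.rint(volume)
        if not np.allclose(volume, rounded):
            raise ValueError(f"label volume {volume_path} holds non-integer values")
        volume = rounded.astype(np.int32)
    table = read_table(labels_path)
    return ParcellationAtlas(label_volume=volume, label_table=table)


def save_atlas(atlas: ParcellationAtlas, volume_path: str | Path,
               labels_path: str | Path) -> None:
    nib.save(nib.Nifti1Image(atlas.label_volume.astype(np.int16), affine=np.eye(4)),
             str(volume_path))
    write_table(atlas.label_table, labels_path)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_run_log(path: str | Path, params: dict, inputs: dict[str, str | Path]) -> Path:
    """Record analysis parameters, package version and input hashes."""
    from . import __version__

    log = {
        "package": "brainentropy",
        "version": __version__,
        "parameters": params,
        "input_hashes": {name: file_sha256(p) for name, p in inputs.items()
                         if p is not None and Path(p).is_file()},
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    return path


def read_config_file(path: str | Path) -> dict[str, str]:
    """Parse a simple ``key=value`` config file ('#' starts a comment)."""
    out: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line (expected key=value): {raw!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out
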