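"""Readers and writers for the plain-text interchange formats.

Reduced small-angle data are conventionally exchanged as three-column ASCII
(`Q I dI`); this module keeps that convention.  Comment lines start with `#`
and carry units and provenance.  A YAML manifest maps sample names to files;
a YAML/JSON contrast config lists the per-sample contrast vectors.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .contrast import ContrastSet, IntensityData, QGrid
from .estimators import PartialEstimate
from .exceptions import GridMismatchError, InvalidInputError
from .kernels import KernelSpec

__all__ = [
    "read_contrast_config", "write_contrast_config",
    "read_intensity_table", "read_intensity_tables", "write_intensity_tables",
    "write_estimate", "read_estimate",
]

#: relative tolerance for "identical" Q columns across files
Q_MATCH_RTOL = 1e-10


def read_contrast_config(path) -> ContrastSet:
    """Load a contrast configuration (YAML or JSON by extension).

    Schema::

        units: 1e-6_A^-2
        components: [core, shell]
        samples:
          - {name: CS100, delta_rho: [-2.36, -5.36]}
    """
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    try:
        components = list(cfg["components"])
        samples = cfg["samples"]
        names = [s["name"] for s in samples]
        deltas = np.array([s["delta_rho"] for s in samples], dtype=float)
    except (KeyError, TypeError) as exc:
        raise InvalidInputError(f"malformed contrast config {path}: {exc}") from exc
    return ContrastSet(tuple(names), deltas, tuple(components))


def write_contrast_config(contrasts: ContrastSet, path) -> None:
    cfg = {
        "units": "1e-6_A^-2",
        "components": list(contrasts.component_names),
        "samples": [
            {"name": name, "delta_rho": [float(x) for x in row]}
            for name, row in zip(contrasts.sample_names, contrasts.deltas)
        ],
    }
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(cfg, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))


def read_intensity_table(path) -> np.ndarray:
    """One `Q I dI` table (whitespace- or comma-delimited, `#` comments).

    Parsed with exact (correctly rounded) float conversion so that write/read
    round trips are bit-identical.
    """
    try:
        arr = np.loadtxt(path, comments="#", ndmin=2)
    except ValueError:
        arr = np.loadtxt(path, comments="#", delimiter=",", ndmin=2)
    if arr.ndim != 2 or arr.shape[1] < 3:
        raise InvalidInputError(f"{path}: expected three columns Q I dI")
    return arr[:, :3]


def read_intensity_tables(manifest_path) -> tuple[IntensityData, list[str]]:
    """Assemble an :class:`IntensityData` from a manifest of per-sample files.

    Manifest (YAML)::

        samples:
          - {name: CS100, file: CS100.dat}

    File paths are resolved relative to the manifest.  All files must share
    one Q column to relative 1e-10; mismatches raise GridMismatchError naming
    the offending files.
    """
    manifest_path = Path(manifest_path)
    manifest = yaml.safe_load(manifest_path.read_text())
    try:
        entries = [(s["name"], s["file"]) for s in manifest["samples"]]
    except (KeyError, TypeError) as exc:
        raise InvalidInputError(f"malformed manifest {manifest_path}: {exc}") from exc
    names, curves = [], []
    qref, ref_file = None, None
    for name, fname in entries:
        arr = read_intensity_table(manifest_path.parent / fname)
        bad = np.nonzero(~(arr[:, 2] > 0))[0]
        if bad.size:
            raise InvalidInputError(
                f"{fname}: non-positive sigma at data rows {bad.tolist()}")
        if qref is None:
            qref, ref_file = arr[:, 0], fname
        elif arr.shape[0] != qref.size or not np.allclose(
                arr[:, 0], qref, rtol=Q_MATCH_RTOL, atol=0.0):
            raise GridMismatchError(
                f"Q grid of {fname} differs from {ref_file}")
        names.append(name)
        curves.append(arr)
    stack = np.array(curves)
    data = IntensityData(QGrid(qref), stack[:, :, 1], stack[:, :, 2])
    return data, names


def write_intensity_tables(data: IntensityData, names, outdir,
                           manifest_name: str = "manifest.yaml") -> Path:
    """Write one `Q I dI` file per sample plus the manifest; returns its path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for n, name in enumerate(names):
        fname = f"{name}.dat"
        arr = np.column_stack([data.qgrid.values, data.intensities[n],
                               data.sigmas[n]])
        header = (f"sample {name}\ncolumns: Q[A^-1] I[abs] dI[1-sigma]")
        np.savetxt(outdir / fname, arr, header=header)
        entries.append({"name": name, "file": fname})
    manifest = outdir / manifest_name
    manifest.write_text(yaml.safe_dump({"samples": entries}, sort_keys=False))
    return manifest


def _estimate_header(est: PartialEstimate, label: str) -> str:
    lines = [f"partial scattering function {label}",
             f"method: {est.method}",
             "columns: Q[A^-1] S[(1e-6 A^-2)^-2 abs] dS[1-sigma]"]
    if est.kernel is not None:
        k = est.kernel
        lines.append(f"kernel: {k.family} alpha={k.alpha:.12g} "
                     f"l={k.length_scale:.12g} tau={k.tau:.12g}")
    if est.log_marginal_likelihood is not None:
        lines.append(f"log_marginal_likelihood: {est.log_marginal_likelihood:.12g}")
    return "\n".join(lines)


def write_estimate(est: PartialEstimate, outdir, prefix: str = "S") -> list[Path]:
    """One `Q S dS` file per partial function; optional covariance dump.

    Returns the written paths.  The covariance (if present on the estimate)
    goes to ``<prefix>_covariance.dat`` with an index legend in its header.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for ell, label in enumerate(est.pair_labels):
        arr = np.column_stack([est.qgrid.values, est.means[ell], est.stderr[ell]])
        path = outdir / f"{prefix}_{label}.dat"
        np.savetxt(path, arr, header=_estimate_header(est, label))
        paths.append(path)
    if est.covariance is not None:
        path = outdir / f"{prefix}_covariance.dat"
        legend = ("posterior covariance, pair-major Q-minor layout: "
                  f"index = pair*M + q_index, M={est.n_q}, "
                  f"pairs={','.join(est.pair_labels)}")
        np.savetxt(path, est.covariance, header=legend)
        paths.append(path)
    return paths


def read_estimate(paths) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read per-pair `Q S dS` files back; returns (Q, means, stderr)."""
    qref = None
    means, stderr = [], []
    for path in paths:
        arr = read_intensity_table(path)  # same 3-column layout
        if qref is None:
            qref = arr[:, 0]
        elif not np.allclose(arr[:, 0], qref, rtol=Q_MATCH_RTOL, atol=0.0):
            raise GridMismatchError(f"Q grid of {path} differs from the first file")
        means.append(arr[:, 1])
        stderr.append(arr[:, 2])
    return qref, np.array(means), np.array(stderr)
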