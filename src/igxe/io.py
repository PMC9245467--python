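"""Dataset and result serialization.

Matrices travel as TSV (tab-delimited, header row of feature names, no row
names); configs, ground truth, and sparse loadings as JSON sidecars.  Every
run directory gets a manifest sufficient to re-run bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .simulate import GroundTruth, OmicsDataset, SimulationConfig
from .stage1 import RegulatoryFit

__all__ = ["write_dataset", "read_dataset", "write_manifest",
           "write_stage1", "read_stage1", "write_gxe_coefficients"]


def _write_matrix(path: Path, M: np.ndarray, names: list[str]) -> None:
    pd.DataFrame(np.atleast_2d(M.T).T if M.ndim == 1 else M,
                 columns=names).to_csv(path, sep="\t", index=False)


def _read_matrix(path: Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if df.isna().any().any():
        rows, cols = np.nonzero(df.isna().to_numpy())
        r, c = int(rows[0]), int(cols[0])
        raise ValueError(
            f"{path.name}: missing value at data row {r + 1}, "
            f"column {df.columns[c]!r}")
    return df.to_numpy(dtype=float), list(df.columns)


def write_dataset(dataset: OmicsDataset, out_dir: str | Path,
                  truth: GroundTruth | None = None,
                  config: SimulationConfig | None = None,
                  seed: int | None = None) -> Path:
    """Write Y/E/G/R TSVs plus a JSON manifest (config, blocks, truth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_matrix(out / "Y.tsv", dataset.Y, ["Y"])
    _write_matrix(out / "E.tsv", dataset.E, dataset.e_names)
    _write_matrix(out / "G.tsv", dataset.G, dataset.g_names)
    _write_matrix(out / "R.tsv", dataset.R, dataset.r_names)
    meta: dict = {"regulator_blocks": list(dataset.regulator_blocks)}
    if config is not None:
        cfg = dataclasses.asdict(config)
        if cfg.get("custom_cov") is not None:
            cfg["custom_cov"] = np.asarray(cfg["custom_cov"]).tolist()
        meta["config"] = cfg
    if seed is not None:
        meta["seed"] = int(seed)
    if truth is not None:
        meta["ground_truth"] = {
            k: np.asarray(v).tolist()
            for k, v in dataclasses.asdict(truth).items()
        }
    write_manifest(out, meta)
    return out


def write_manifest(out_dir: str | Path, payload: dict) -> Path:
    path = Path(out_dir) / "manifest.json"
    payload = dict(payload)
    payload.setdefault("software_version", __version__)
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path


def read_dataset(in_dir: str | Path) -> tuple[OmicsDataset, GroundTruth | None]:
    """Read a dataset directory written by :func:`write_dataset`.

    Regulator block sizes come from the manifest when present, otherwise
    they are inferred from column-name prefixes (DM*/CNA*), falling back to
    an even split.
    """
    d = Path(in_dir)
    Y, _ = _read_matrix(d / "Y.tsv")
    E, e_names = _read_matrix(d / "E.tsv")
    G, g_names = _read_matrix(d / "G.tsv")
    R, r_names = _read_matrix(d / "R.tsv")
    Y = Y.ravel()
    n = Y.shape[0]
    for name, M in (("E", E), ("G", G), ("R", R)):
        if M.shape[0] != n:
            raise ValueError(f"{name}.tsv has {M.shape[0]} rows but Y.tsv has {n}")
    manifest = d / "manifest.json"
    truth = None
    if manifest.exists():
        meta = json.loads(manifest.read_text())
        blocks = tuple(meta.get("regulator_blocks",
                                (R.shape[1] // 2, R.shape[1] - R.shape[1] // 2)))
        gt = meta.get("ground_truth")
        if gt is not None:
            truth = GroundTruth(**{k: np.asarray(v) for k, v in gt.items()})
    else:
        n_dm = sum(1 for c in r_names if c.upper().startswith("DM"))
        if 0 < n_dm < R.shape[1]:
            blocks = (n_dm, R.shape[1] - n_dm)
        else:
            blocks = (R.shape[1] // 2, R.shape[1] - R.shape[1] // 2)
    dataset = OmicsDataset(Y=Y, E=E, G=G, R=R, regulator_blocks=blocks,
                           g_names=g_names, r_names=r_names, e_names=e_names)
    return dataset, truth


def write_stage1(fit: RegulatoryFit, out_dir: str | Path) -> Path:
    """Theta_hat as TSV; components as JSON with sparse index:value maps."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p_g = fit.Theta_hat.shape[1]
    _write_matrix(out / "Theta_hat.tsv", fit.Theta_hat,
                  [f"G{j+1}" for j in range(p_g)])
    lrms = []
    for d, u, v in fit.lrm_list:
        lrms.append({
            "d": d,
            "u": {int(i): float(u[i]) for i in np.nonzero(u)[0]},
            "v": {int(j): float(v[j]) for j in np.nonzero(v)[0]},
        })
    payload = {
        "L": fit.L,
        "p_r": int(fit.Theta_hat.shape[0]),
        "p_g": int(p_g),
        "lambda_svd": fit.lambda_svd,
        "intercepts": fit.intercepts.tolist(),
        "lrms": lrms,
    }
    (out / "lrms.json").write_text(json.dumps(payload, indent=1))
    return out


def read_stage1(in_dir: str | Path) -> RegulatoryFit:
    d = Path(in_dir)
    Theta, _ = _read_matrix(d / "Theta_hat.tsv")
    meta = json.loads((d / "lrms.json").read_text())
    p_r, p_g, L = meta["p_r"], meta["p_g"], meta["L"]
    dvals = np.zeros(L)
    U = np.zeros((p_r, L))
    V = np.zeros((p_g, L))
    for l, rec in enumerate(meta["lrms"]):
        dvals[l] = rec["d"]
        for i, val in rec["u"].items():
            U[int(i), l] = val
        for j, val in rec["v"].items():
            V[int(j), l] = val
    return RegulatoryFit(Theta_hat=Theta,
                         intercepts=np.asarray(meta["intercepts"], float),
                         d=dvals, U=U, V=V, lambda_svd=meta.get("lambda_svd"))


def write_gxe_coefficients(fit, q: int, out_dir: str | Path) -> Path:
    """Coefficient tables: alpha.tsv, b1.tsv, b2.tsv, gamma.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    slots = ["main"] + [f"E{k+1}" for k in range(q)]
    pd.DataFrame({"alpha": fit.alpha_hat}).to_csv(out / "alpha.tsv", sep="\t",
                                                  index=False)
    pd.DataFrame(fit.b1_hat.reshape(-1, q + 1), columns=slots).to_csv(
        out / "b1.tsv", sep="\t", index=False)
    pd.DataFrame(fit.b2_hat.reshape(-1, q + 1), columns=slots).to_csv(
        out / "b2.tsv", sep="\t", index=False)
    pd.DataFrame({"gamma": fit.gamma_hat}).to_csv(out / "gamma.tsv", sep="\t",
                                                  index=False)
    return out
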