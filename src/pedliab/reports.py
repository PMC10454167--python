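"""Publication-style outputs: summary/draws CSVs, trace plots, manifest."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .sampler import FitResult

__all__ = ["write_fit_outputs"]

# column order mirrors the published parameter tables
_TABLE_ORDER_PREFIX = [
    "h2", "c2_sibs", "c2_mother_off", "c2_father_off", "c2_spouses",
    "c2_total", "e2", "h2_gxe",
]


def _ordered(table):
    order = {name: i for i, name in enumerate(_TABLE_ORDER_PREFIX)}
    key = table["parameter"].map(lambda p: (order.get(p, len(order)), p))
    return table.iloc[np.argsort(key.to_numpy(), kind="stable")]


def write_fit_outputs(result: FitResult, out_dir, seed: int,
                      config_dict: dict | None = None,
                      make_plots: bool = True) -> dict[str, str]:
    """Write summary.csv, draws.csv, diagnostics.csv, trace plots and a
    reproducibility manifest into ``out_dir``; returns the file map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}

    summary = result.summary()
    table = _ordered(summary.table)
    summary_path = out / "summary.csv"
    table[["parameter", "median", "sd", "hpd_low", "hpd_high"]].to_csv(
        summary_path, index=False)
    files["summary"] = str(summary_path)

    diag_path = out / "diagnostics.csv"
    table[["parameter", "rhat", "ess"]].to_csv(diag_path, index=False)
    files["diagnostics"] = str(diag_path)

    draws_path = out / "draws.csv"
    result.draws.to_dataframe().to_csv(draws_path, index=False)
    files["draws"] = str(draws_path)

    if make_plots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        names = list(result.draws.params)
        fig, axes = plt.subplots(len(names), 1, figsize=(8, 1.8 * len(names)),
                                 squeeze=False)
        for ax, name in zip(axes[:, 0], names):
            arr = result.draws[name]
            for ch in range(arr.shape[0]):
                ax.plot(arr[ch], lw=0.4)
            ax.set_ylabel(name, fontsize=7)
        fig.tight_layout()
        trace_path = out / "trace.png"
        fig.savefig(trace_path, dpi=110)
        plt.close(fig)
        files["trace"] = str(trace_path)

    cfg = config_dict or {}
    manifest = {
        "seed": seed,
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest(),
        "n_chains": result.draws.config.n_chains,
        "n_warmup": result.draws.config.n_warmup,
        "n_sampling": result.draws.config.n_sampling,
        "threshold": result.model.threshold,
        "n_families": len(result.model.families),
        "n_individuals": int(result.model.packed.n_individuals),
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    files["manifest"] = str(manifest_path)
    return files
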