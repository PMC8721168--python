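"""Headless plots over finished pipeline outputs (PNG files)."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .errors import ValidationError  # noqa: E402


def plot_run(outdir: str | Path) -> list[Path]:
    out = Path(outdir)
    if not out.exists():
        raise ValidationError(f"pipeline output directory {out} does not exist")
    made: list[Path] = []
    pca_path = out / "pca_scores.tsv"
    if pca_path.exists():
        df = pd.read_csv(pca_path, sep="\t", comment="#", index_col=0)
        fig, ax = plt.subplots(figsize=(5, 4))
        for pop, grp in df.groupby("population"):
            ax.scatter(grp["PC1"], grp["PC2"], label=str(pop), s=25)
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        ax.legend(frameon=False)
        fig.tight_layout()
        p = out / "pca.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        made.append(p)
    win_path = out / "windows.tsv"
    if win_path.exists():
        w = pd.read_csv(win_path, sep="\t")
        fst_cols = [c for c in w.columns if c.startswith("fst_")]
        if fst_cols:
            fig, ax = plt.subplots(figsize=(7, 3))
            ax.plot(np.arange(len(w)), w[fst_cols[0]], ".", ms=2)
            ax.set_xlabel("window index")
            ax.set_ylabel(fst_cols[0])
            fig.tight_layout()
            p = out / "fst_scan.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            made.append(p)
    deg_path = out / "deg_table.tsv"
    if deg_path.exists():
        d = pd.read_csv(deg_path, sep="\t", index_col=0)
        fig, ax = plt.subplots(figsize=(5, 4))
        colors = np.where(d["call"] == "up", "tab:red",
                          np.where(d["call"] == "down", "tab:blue", "0.7"))
        ax.scatter(d["log2fc"], -np.log10(np.maximum(d["p"], 1e-300)), c=colors, s=6)
        ax.set_xlabel("log2 fold change")
        ax.set_ylabel("-log10 p")
        fig.tight_layout()
        p = out / "volcano.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        made.append(p)
    return made
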