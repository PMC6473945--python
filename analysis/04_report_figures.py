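"""Render the summary figures: Kratky evolution, fitted time courses,
and reaction-diffusion gel kinetics, under results/figures/."""

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from clexsaxs.saxs_io import read_profile, read_series, subtract_buffer, to_kratky

ROOT = Path(__file__).resolve().parents[1] / "results"
FIG = ROOT / "figures"


def kratky_overlay(label: str) -> None:
    d = ROOT / "fixtures" / label
    frames = read_series(d / "manifest.csv")
    buf = read_profile(d / "buffer.dat")
    fig, ax = plt.subplots(figsize=(6, 4))
    cmap = plt.get_cmap("viridis")
    for f in frames[:-1]:
        k = to_kratky(subtract_buffer(f, buf))
        ax.plot(k.q, k.y, lw=0.7, color=cmap(f.time / frames[-2].time))
    k = to_kratky(subtract_buffer(frames[-1], buf))
    ax.plot(k.q, k.y, lw=1.5, color="k", label="full gel (10 h)")
    ax.set_xlabel("q (nm$^{-1}$)")
    ax.set_ylabel("$q^2 I(q)$")
    ax.set_title(f"Kratky evolution, {label}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(FIG / f"kratky_{label}.png", dpi=150)
    plt.close(fig)


def timecourse_figure() -> None:
    fig, axes = plt.subplots(2, 1, figsize=(6, 7), sharex=True)
    for label in ["pH7.0-averaged", "pH7.4", "pH8.0"]:
        path = ROOT / "timecourses" / f"{label}.csv"
        if not path.exists():
            continue
        t = pd.read_csv(path)
        early = t[t["time_s"] < 1000]
        axes[0].plot(early["time_s"], early["rc1_nm"], "o-", ms=3, label=f"$R_{{c1}}$ {label}")
        axes[0].plot(early["time_s"], early["rc2_nm"], "s--", ms=3, label=f"$R_{{c2}}$ {label}")
        axes[1].plot(early["time_s"], early["w2"], "o-", ms=3, label=label)
    axes[0].set_ylabel("cross-sectional radius (nm)")
    axes[1].set_ylabel("junction-zone weight fraction $w_2$")
    axes[1].set_xlabel("time (s)")
    for ax in axes:
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(FIG / "timecourses.png", dpi=150)
    plt.close(fig)


def rd_figure() -> None:
    roi_path = ROOT / "rd" / "roi.csv"
    if not roi_path.exists():
        return
    roi = pd.read_csv(roi_path)
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, grp in roi.groupby("roi_label"):
        ax.plot(grp["t_s"], grp["gel_M"], "o-", label=label)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("gel (M monomer)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(FIG / "rd_roi.png", dpi=150)
    plt.close(fig)


def main() -> None:
    FIG.mkdir(parents=True, exist_ok=True)
    for label in ["pH7.0-rep1", "pH8.0"]:
        if (ROOT / "fixtures" / label).exists():
            kratky_overlay(label)
    timecourse_figure()
    rd_figure()
    print(f"figures written to {FIG}")


if __name__ == "__main__":
    main()
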