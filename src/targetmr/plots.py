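"""Regional association plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .gwas_io import SummaryStatsTable


def regional_manhattan(stats: SummaryStatsTable, path: str,
                       highlight: str | None = None,
                       title: str | None = None) -> None:
    """Scatter of -log10 p against position for one trait over a region."""
    pos = np.array([r.pos for r in stats.records]) / 1e6
    logp = -np.log10([r.pval for r in stats.records])
    fig, ax = plt.subplots(figsize=(7, 3.2))
    ax.scatter(pos, logp, s=12, c="steelblue", alpha=0.8)
    if highlight is not None:
        rec = stats.get(highlight)
        ax.scatter([rec.pos / 1e6], [-np.log10(rec.pval)], s=40,
                   c="purple", zorder=3, label=highlight)
        ax.legend(frameon=False)
    ax.set_xlabel("position (Mb)")
    ax.set_ylabel(r"$-\log_{10} p$")
    ax.set_title(title or stats.trait_name)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def coloc_scatter(stats1: SummaryStatsTable, stats2: SummaryStatsTable,
                  path: str) -> None:
    """Per-variant -log10 p of trait 2 against trait 1 over shared variants."""
    shared = [v for v in stats1.variant_ids if v in set(stats2.variant_ids)]
    p1 = -np.log10([stats1.get(v).pval for v in shared])
    p2 = -np.log10([stats2.get(v).pval for v in shared])
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(p1, p2, s=12, c="dimgray", alpha=0.8)
    ax.set_xlabel(f"{stats1.trait_name}  $-\\log_{{10}} p$")
    ax.set_ylabel(f"{stats2.trait_name}  $-\\log_{{10}} p$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
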