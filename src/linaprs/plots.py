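"""Optional figure helpers: Manhattan-style importance plots and real/decoy
score density plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .interpret import ImportanceTable


def manhattan(table: ImportanceTable, trait, ax=None, thresholds: dict | None = None):
    """Importance scores along the panel; decoys in orange, reals in grey/black
    alternating by chromosome."""
    t = table.trait_index(trait)
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    x = np.arange(len(table.snp_ids))
    real = ~table.is_decoy
    chroms = np.asarray(table.chromosomes)
    shade = np.array([hash(c) % 2 for c in chroms], dtype=bool)
    ax.scatter(x[real & shade], table.scores[t, real & shade], s=4, c="black")
    ax.scatter(x[real & ~shade], table.scores[t, real & ~shade], s=4, c="grey")
    ax.scatter(x[~real], table.scores[t, ~real], s=4, c="tab:orange", label="decoy")
    for label, thr in (thresholds or {}).items():
        ax.axhline(thr, ls=":", label=label)
    ax.set_xlabel("SNP index")
    ax.set_ylabel("importance score")
    ax.set_title(str(table.trait_names[t]))
    ax.legend(loc="upper right", fontsize=8)
    return ax


def score_density(table: ImportanceTable, trait, ax=None, bins: int = 60):
    """Overlaid histograms of real vs decoy importance scores (log counts)."""
    t = table.trait_index(trait)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    real = ~table.is_decoy
    edges = np.histogram_bin_edges(table.scores[t], bins=bins)
    ax.hist(table.scores[t, real], bins=edges, histtype="step", color="black",
            label="real", log=True)
    ax.hist(table.scores[t, ~real], bins=edges, histtype="step", color="tab:orange",
            label="decoy", log=True)
    ax.set_xlabel("importance score")
    ax.set_ylabel("SNP count")
    ax.legend(fontsize=8)
    return ax
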