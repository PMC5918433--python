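"""Ranking and precision/recall evaluation against a truth set.

A candidate call is *correct* when it matches a truth variant in
sequence and position — zygosity is not compared.  Candidates are ranked
by marginal log-odds (the posterior is monotone in the odds, so the two
orderings coincide) and precision is reported at rank cutoffs in
increments of 50 calls.
"""

from __future__ import annotations

from dataclasses import dataclass

DEFAULT_STEP = 50


@dataclass(frozen=True)
class PRPoint:
    cutoff: int  # number of top-ranked calls considered
    n_true: int  # correct calls among them
    precision: float


def rank_variants(scored: list, key=None) -> list:
    """Descending by log-odds; ties broken by (contig, pos, ref, alt)."""
    if key is None:
        key = lambda s: s.log_odds  # noqa: E731
    return sorted(
        scored,
        key=lambda s: (
            -key(s),
            s.variant.contig,
            s.variant.pos,
            s.variant.ref_allele,
            s.variant.alt_allele,
        ),
    )


def precision_recall(
    ranked: list,
    truth_keys: set[tuple],
    step: int = DEFAULT_STEP,
) -> list[PRPoint]:
    """Precision among the top-c calls for c = step, 2*step, ..., n.

    A final partial increment is emitted so the last point always covers
    the whole ranked list; at full recall the precision equals the
    overall callset precision.
    """
    points: list[PRPoint] = []
    n_true = 0
    for i, s in enumerate(ranked, start=1):
        if s.variant.key() in truth_keys:
            n_true += 1
        if i % step == 0 or i == len(ranked):
            points.append(PRPoint(i, n_true, n_true / i))
    return points


def write_pr_table(points: list[PRPoint], path) -> None:
    with open(path, "w") as out:
        out.write("cutoff\tn_true\tprecision\n")
        for p in points:
            out.write(f"{p.cutoff}\t{p.n_true}\t{p.precision:.6g}\n")


def plot_pr(points: list[PRPoint], path) -> None:
    """Optional precision-vs-rank plot (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot([p.cutoff for p in points], [p.precision for p in points], "o-")
    ax.set_xlabel("rank cutoff (calls)")
    ax.set_ylabel("precision")
    ax.set_ylim(0, 1.05)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
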