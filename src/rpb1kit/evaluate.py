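"""Ground-truth evaluation of pipeline runs on simulated data."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .marker import ReferenceSet


def detectable_chimeras(
    truth: pd.DataFrame, reference: ReferenceSet, min_side_diffs: int = 3
) -> set[str]:
    """Chimeric reads that carry a recoverable crossover signal.

    A chimera is detectable only if both parent segments differ from the
    other parent at ``min_side_diffs`` or more sites within the read: with
    fewer diagnostic sites on its minor side, the molecule is within
    sequencing-error distance of a pure parent read and no de novo
    detector can (or needs to) flag it — it simply clusters with the
    parent.  This mirrors how chimera-detection benchmarks stratify
    sensitivity by the number of differences.
    """
    iso_seq = {rec.id: rec.ungapped for rec in reference.records}
    tr = truth.set_index("read_id")
    out: set[str] = set()
    for row in truth[truth["is_chimera"]].itertuples():
        ta = iso_seq[tr.loc[row.parent_a, "isolate"]]
        tb = iso_seq[tr.loc[row.parent_b, "isolate"]]
        x = int(row.crossover)
        L = min(int(row.template_len), len(ta), len(tb))
        diffs = np.frombuffer(ta[:L].encode(), dtype=np.uint8) != np.frombuffer(
            tb[:L].encode(), dtype=np.uint8
        )
        left = int(diffs[:x].sum())
        right = int(diffs[x:].sum())
        if left >= min_side_diffs and right >= min_side_diffs:
            out.add(row.read_id)
    return out


def chimera_confusion(
    truth: pd.DataFrame,
    screened_read_ids: frozenset | set,
    flagged_read_ids: frozenset | set,
    reference: ReferenceSet | None = None,
    min_side_diffs: int = 3,
) -> dict:
    """Read-level chimera detection recall and false-positive rate.

    Only reads that reached the chimera stage (i.e. survived the earlier
    filters) enter the confusion counts.  ``recall`` is over detectable
    chimeras (see :func:`detectable_chimeras`) when a reference set is
    given, and ``recall_all`` over every chimeric read; the
    false-positive rate is over true non-chimeras.
    """
    reached = truth[truth["read_id"].isin(screened_read_ids)]
    chim = reached[reached["is_chimera"]]
    clean = reached[~reached["is_chimera"]]
    tp = int(chim["read_id"].isin(flagged_read_ids).sum())
    fp = int(clean["read_id"].isin(flagged_read_ids).sum())
    result = {
        "n_chimeric": len(chim),
        "n_clean": len(clean),
        "true_positives": tp,
        "false_positives": fp,
        "recall_all": tp / len(chim) if len(chim) else float("nan"),
        "false_positive_rate": fp / len(clean) if len(clean) else float("nan"),
    }
    if reference is not None:
        det = detectable_chimeras(truth, reference, min_side_diffs)
        det_reached = chim[chim["read_id"].isin(det)]
        tp_det = int(det_reached["read_id"].isin(flagged_read_ids).sum())
        result["n_detectable"] = len(det_reached)
        result["recall"] = (
            tp_det / len(det_reached) if len(det_reached) else float("nan")
        )
    return result


def mt_recovery(mts: list, truth: pd.DataFrame) -> dict:
    """Compare recovered molecular taxa against the simulated species."""
    true_species = sorted(
        s for s in truth["species"].dropna().unique() if s and not s.startswith("Fusarium")
    )
    mt_names = sorted(m.name for m in mts)
    return {
        "n_true_species": len(true_species),
        "n_mts": len(mts),
        "mt_names": mt_names,
        "species_recovered": sorted(set(true_species) & set(mt_names)),
    }
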