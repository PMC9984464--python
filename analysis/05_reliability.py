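"""Within- vs between-participant reliability of responses and scores.

Compares same-participant cross-session agreement against cross-participant
agreement, for target-tone response curves (Pearson r) and for entrainment
scores (absolute difference), with Mann-Whitney U and Cohen's d.
"""

import pandas as pd

import common
import pupilsync as ps


def main():
    curves, score_map = {}, {}
    for p in range(common.N_PARTICIPANTS):
        for s in range(common.N_SESSIONS):
            seq, ts, _ = common.make_session(p, s)
            clean = ps.clean_for_trials(ts)
            trials = ps.segment_trials(clean, seq)
            curve = ps.condition_average(trials, "target")
            if curve is not None:
                curves.setdefault(p, {})[s] = curve
            spline = ps.interpolate_gaps(ts, "cubic_spline")
            score_map.setdefault(p, {})[s] = ps.entrainment_score(
                common.split_blocks(spline)
            ).score

    rows = []
    cr = ps.curve_reliability(curves)
    rows.append(("target_curves", "pearson_r", cr.U, cr.p, cr.d,
                 cr.n_within, cr.n_between,
                 round(cr.mean_within, 3), round(cr.mean_between, 3)))
    sr = ps.score_reliability(score_map)
    rows.append(("entrainment_scores", "abs_difference", sr.U, sr.p, sr.d,
                 sr.n_within, sr.n_between,
                 round(sr.mean_within, 3), round(sr.mean_between, 3)))
    out = pd.DataFrame(
        rows,
        columns=["measure", "statistic", "U", "p", "d",
                 "n_within", "n_between", "mean_within", "mean_between"],
    )
    out.to_csv(common.RESULTS / "reliability_summary.tsv", sep="\t", index=False)
    print(out.to_string(index=False))
    print(
        "\ncurves: within-participant correlations should exceed between; "
        "scores: within differences should be smaller (d < 0)"
    )


if __name__ == "__main__":
    main()
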