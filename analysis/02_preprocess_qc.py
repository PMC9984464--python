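"""Clean every session and apply the quality-control rules.

Sessions missing more than 90% of samples are unusable; listening traces
needing more than 25% interpolation are excluded from dyadic analysis.
The demo cohort's blink rates sit well inside both limits, so the QC
report documents clean data rather than exclusions.
"""

import pandas as pd

import common
import pupilsync as ps


def main():
    rows = []
    for p in range(common.N_PARTICIPANTS):
        for s in range(common.N_SESSIONS):
            _, ts, _ = common.make_session(p, s)
            verdict = ps.session_qc(ts)
            clean = ps.interpolate_gaps(ts, "linear")
            listener = ps.listener_qc(clean)
            rows.append(
                (
                    p,
                    s,
                    round(verdict.missing_fraction, 4),
                    round(clean.interpolated_fraction, 4),
                    verdict.usable,
                    listener.usable,
                    verdict.reason or listener.reason,
                )
            )
    qc = pd.DataFrame(
        rows,
        columns=[
            "participant", "session", "missing_fraction",
            "interpolated_fraction", "session_usable", "listener_usable", "reason",
        ],
    )
    qc.to_csv(common.RESULTS / "qc_report.tsv", sep="\t", index=False)
    n_bad = (~qc["session_usable"]).sum()
    print(qc.to_string(index=False))
    print(f"\n{n_bad} of {len(qc)} sessions excluded; report in results/qc_report.tsv")


if __name__ == "__main__":
    main()
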