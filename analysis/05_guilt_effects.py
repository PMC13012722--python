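"""The guilt-effect inference stage.

Restricts happiness probes to lottery outcomes in the social and partner
conditions, fits the mixed model with the partner-outcome x decision-maker
interaction, computes the stratified guilt contrasts with Bayes factors,
the agency effect, and the paired-t sample size a follow-up study would
need at the observed effect size.
"""
import json

from _common import RESULTS, load_or_simulate

from socdec import guilt


def main() -> None:
    ds = load_or_simulate()
    RESULTS.mkdir(exist_ok=True)

    rows = guilt.build_post_lottery_table(ds)
    rows.to_csv(RESULTS / "post_lottery_table.csv", index=False)
    lmm = guilt.fit_guilt_lmm(rows)
    lmm.to_csv(RESULTS / "guilt_lmm.csv", index=False)
    inter = lmm[lmm["term"] == "pHigh:sDec"].iloc[0]
    print(f"{len(rows)} post-lottery probes from {rows['participant'].nunique()} "
          "participants")
    print(f"pHigh x sDec interaction: beta = {inter['beta']:.3f}, "
          f"t({inter['df']}) = {inter['t']:.2f}, p = {inter['p']:.2e} — "
          "partner outcomes matter more after own choices")

    eff = guilt.guilt_effect(ds)
    eff.per_participant.to_csv(RESULTS / "guilt_effect_participants.csv",
                               index=False)
    summary = {}
    for stratum, e in eff.strata.items():
        summary[stratum] = e.__dict__
        print(f"guilt effect [{stratum}]: {e.mean_effect:+.3f} z-units, "
              f"t({e.df}) = {e.t:.2f}, p = {e.p:.4f}, d = {e.cohens_d:.2f}, "
              f"BF10 = {e.bf10:.1f}")

    agency = guilt.agency_effect(ds)
    beta = float(agency.loc[agency["term"] == "agency", "beta"].iloc[0])
    summary["agency_beta"] = beta
    print(f"agency effect (chose vs did not choose): beta = {beta:+.3f}")

    d_planning = abs(eff.strata["self_high"].cohens_d)
    if d_planning > 0:
        n_next = guilt.required_sample_size_paired(d_planning, 0.05, 0.95)
        summary["required_n_at_observed_d"] = n_next
        print(f"a follow-up powered at 95% for the observed self-high d "
              f"({d_planning:.2f}) would need n = {n_next}")
    (RESULTS / "guilt_summary.json").write_text(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
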