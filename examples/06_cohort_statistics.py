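"""Cohort statistics on the shipped printed-table fixtures.

Nine stage-D survival times give Kaplan–Meier medians per arm and a
log-rank test; the adverse-event table gives per-arm incidences and a
Yates-corrected chi-square.
"""

from netscreen import (
    Contingency2x2, chi2_2x2, incidence, km_curve,
    load_stage_d_fixture, load_trae_fixture, logrank,
)

df = load_stage_d_fixture()
for arm in ("exposure", "nonexposure"):
    km = km_curve(df, arm)
    print(f"{arm}: n={km.n}, KM median {km.median:.0f} days")
stat, p = logrank(df)
print(f"log-rank: chi2={stat:.3f}, p={p:.3f}  (tiny n; underpowered by design)")

trae = load_trae_fixture()
row = trae[trae["trae"] == "Leukopenia"].iloc[0]
tbl = Contingency2x2(
    int(row["exposure_events"]), int(row["exposure_n"] - row["exposure_events"]),
    int(row["nonexposure_events"]), int(row["nonexposure_n"] - row["nonexposure_events"]),
)
c, cp = chi2_2x2(tbl)
print(f"leukopenia: {incidence(tbl, 'exposure')}% vs {incidence(tbl, 'nonexposure')}%, "
      f"Yates chi2={c:.2f}, p={cp:.3f}")
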