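"""Render the five rule-based AGP summarization tasks for one case.

The analyzers emit structured facts plus a deterministic 2-6 sentence
narrative per task: data quality, hyperglycemia, hypoglycemia, glycemic
variability, and the main clinical concern.  Every number in a narrative
is traceable to the facts, severity adjectives are threshold-gated, and
nocturnal / level-2 hypoglycemia always surface.
"""

from cgmkit import CaseConfig, generate_case, metric_report, summarize_case

case = generate_case(CaseConfig(case_id="demo", target_gmi=6.2, seed=42))
report = metric_report(case.series, expected_days=14)
findings = summarize_case(case.series, report)

for task, finding in findings.items():
    print(f"--- {task}  (flags: {', '.join(finding.flags) or 'none'})")
    print(finding.narrative, "\n")
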