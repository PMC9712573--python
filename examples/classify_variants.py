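"""Classify variants from ACMG evidence tokens, two ways at once.

Runs the categorical 2015 combining rules and the odds-of-pathogenicity
posterior on a handful of evidence profiles and prints both results. The
last profile shows the discordance phenomenon: enough moderate/supporting
evidence to reach a pathogenic posterior (>= 0.99), yet the rule table
stops at class 4 because no strong criterion is present.
"""

from tikd import classify, parse_evidence
from tikd.acmg import format_posterior

PROFILES = [
    ("PVS1;PS1", "canonical splice + established functional damage"),
    ("PS1;PM1;PM2", "one strong, two moderate"),
    ("PM1;PM2;PP1;PP2", "the modal likely-pathogenic combination"),
    ("PM1;PM2;PM3;PP1;PP2;PP3;PP4", "moderate/supporting pile-up"),
    ("BS1;BP1", "benign-leaning evidence"),
]

print(f"{'evidence':<30} {'class':>5} {'posterior':>9}  flags")
for tokens, note in PROFILES:
    result = classify(parse_evidence(tokens))
    flag = "DISCORDANT" if result.discordant else ""
    print(
        f"{tokens:<30} {result.categorical_class:>5} "
        f"{format_posterior(result.posterior):>9}  {flag:<11} # {note}"
    )

print(
    "\nclass: categorical five-tier result (5 pathogenic ... 1 benign);"
    "\nposterior: probability of pathogenicity at prior 0.10, odds 350 per"
    " very-strong criterion; DISCORDANT marks posteriors >= 0.99 that the"
    " combining rules cap at class 4."
)
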