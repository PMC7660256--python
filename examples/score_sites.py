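"""Score 17-bp sites against the PdhR box and render them.

The box AATTGGTnnnACCAATT has 14 informative positions (the 3-bp spacer
is unconstrained). The conservation score counts how many informative
positions match; the rendering uppercases exactly the matching ones.
"""

from regulonscan import render_match, score_against_box

sites = [
    "AATTGGTAAGACCAATT",  # the site in the aroP/pdhR divergent spacer
    "AATTGGTATAACCAATG",  # upstream of the cyoABCDE operon
    "TCCTGGTCATAGCACCT",  # the fadE/lpcA spacer site
    "CGTTAGCCACGCCAACA",  # weak intragenic site near deoC
]

print(f"{'site':20s} {'rendered':20s} conservation")
for site in sites:
    score = score_against_box(site)
    print(f"{site:20s} {render_match(site):20s} {score.rendered}")

# A 14/14 site matches the box at every informative position; scores
# around 7/14 are at the floor of what the screen reports as a motif.
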