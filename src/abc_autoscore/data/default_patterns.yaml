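# Default pattern configuration for the automated Addiction Behaviors Checklist.
#
# RECONSTRUCTED DEFAULTS: the original instrument's full lexicons and expression
# set are not distributed with this package.  These lexicons and the 27
# expressions below were authored against the 20 published checklist item texts
# and the documented filtering rules (opioid-context terms such as "pain med",
# "opioid", "opiod", "narc", "analges"; hoarding stems "hoard", "stash",
# "left over", "storing", "stockpil"; a 7-term negation lexicon; the
# "discharge instructions" false-positive exclusion).  Sites should review and
# extend them against their own documentation styles.
#
# Intentional misspellings ("opiod", "stockpil", "analges") are lexicon
# entries, not typos.

lexicons:
  opioid_terms:
    - pain med
    - pain pill
    - opioid
    - opiod
    - opiate
    - narc
    - analges
  negation_terms:
    - denies
    - denied
    - "no"
    - "not"
    - without
    - never
    - negative for
  drug_names:
    - oxycodone
    - oxycontin
    - roxicodone
    - hydrocodone
    - vicodin
    - norco
    - lortab
    - percocet
    - morphine
    - ms contin
    - fentanyl
    - duragesic
    - codeine
    - tramadol
    - methadone
    - buprenorphine
    - suboxone
    - hydromorphone
    - dilaudid
    - oxymorphone
    - opana
    - tapentadol
    - meperidine
    - demerol
    - heroin

items:
  - item_id: 1
    label: "Patient used illicit drugs or evidences problem drinking"
    core_expressions:
      - '\billicit\s+(?:drug|substance)\w*'
      - '\bproblem\s+drink\w+'
    require_opioid_context: false
  - item_id: 2
    label: "Patient has hoarded medications"
    core_expressions:
      - '\b(?:hoard\w*|stash\w*|left\s?over|storing|stockpil\w*)\b'
    require_opioid_context: true
    opioid_order_constraint: trigger_before_term
  - item_id: 3
    label: "Patient used more narcotics than prescribed"
    core_expressions:
      - '\b(?:used?|using|took|takes?|taking)\s+more\b[^.\n]{0,40}\bthan\s+(?:prescribed|directed)\b'
    require_opioid_context: true
  - item_id: 4
    label: "Patient ran out of medications early"
    core_expressions:
      - '\br(?:an|uns|unning)\s+out\b[^.\n]{0,50}\bearly\b'
      - '\bearly\s+refill\w*'
    require_opioid_context: true
  - item_id: 5
    label: "Patient has increased use of narcotics"
    core_expressions:
      - '\bincreas\w*\s+(?:use|usage|dose|dosage|amount|intake)\b'
    require_opioid_context: true
  - item_id: 6
    label: "Patient used analgesics PRN when prescription is for time-contingent use"
    core_expressions:
      - '\bprn\b[^.\n]{0,50}\b(?:instead\s+of|rather\s+than)\s+(?:as\s+)?scheduled\b'
      - '\btime[-\s]contingent\b'
    require_opioid_context: true
  - item_id: 7
    label: "Patient received narcotics from more than one provider"
    core_expressions:
      - '\bfrom\s+(?:more\s+than\s+one|multiple|several|another|other)\s+(?:provider|prescriber|physician|doctor|clinic)s?\b'
    require_opioid_context: true
  - item_id: 8
    label: "Patient bought medications on the street"
    core_expressions:
      - '\b(?:buy|buys|buying|bought|purchas\w+|obtain\w*|got)\b[^.\n]{0,40}\b(?:on|off)\s+the\s+street\w*'
    require_opioid_context: true
  - item_id: 9
    label: "Patient appears sedated or confused"
    core_expressions:
      - '\b(?:sedated|somnolent|slurred\s+speech|nodding\s+off)\b'
      - '\b(?:overmedicat\w+|oversedat\w+)\b'
    require_opioid_context: false
  - item_id: 10
    label: "Patient expresses worries about addiction"
    core_expressions:
      - '\b(?:worri\w+|worry|concern\w*|afraid|fear\w*)\b[^.\n]{0,40}\b(?:addict\w+|dependen\w+)\b'
    require_opioid_context: false
  - item_id: 11
    label: "Patient expresses concern about future availability of narcotics"
    core_expressions:
      - '\bfuture\s+availability\b'
      - '\b(?:enough|sufficient)\s+(?:pain\s+)?(?:med\w*|pills?|opioid\w*)\s+(?:until|to\s+last)\b'
    require_opioid_context: true
  - item_id: 12
    label: "Patient reports lost or stolen medications"
    core_expressions:
      - '\b(?:lost|stolen|misplaced)\b'
    require_opioid_context: true
  - item_id: 13
    label: "Patient indicates needing or having to have analgesic medications"
    core_expressions:
      - '\b(?:needs|must\s+have)\b'
    require_opioid_context: true
    opioid_order_constraint: trigger_before_term
  - item_id: 14
    label: "Discussion of analgesic medications was the predominant issue of visit"
    core_expressions:
      - '\bpredominant\s+(?:issue|topic|focus)\b'
      - '\b(?:main|primary)\s+(?:topic|focus)\s+of\s+(?:the\s+)?visit\b'
    require_opioid_context: true
  - item_id: 15
    label: "Patient exhibits noncompliance with recommended therapies"
    core_expressions:
      - '\bnon-?complian\w+\b'
    require_opioid_context: false
  - item_id: 16
    label: "Patient hostile or angry when discussing medications"
    core_expressions:
      - '\b(?:hostile|angry|irate|belligerent)\b'
    require_opioid_context: true
  - item_id: 17
    label: "Significant others express concern about patient's medication use"
    core_expressions:
      - '\b(?:wife|husband|spouse|partner|family|mother|father|daughter|son)\b[^.\n]{0,50}\bconcern\w*\b'
    require_opioid_context: true
  - item_id: 18
    label: "Patient has difficulty with medication agreement"
    core_expressions:
      - '\b(?:medication|narcotic|opioid|pain|controlled\s+substance)\s+(?:agreement|contract)\b'
    require_opioid_context: false
  - item_id: 19
    label: "Patient requests specific medications by name"
    core_expressions:
      - '\b(?:request\w*|ask\w*\s+for)\b[^.\n]{0,40}\bby\s+name\b'
      - '\brequest\w*\s+(?:a\s+)?specific\b'
    require_opioid_context: true
  - item_id: 20
    label: "Urine drug screen inconsistent with prescribed regimen"
    core_expressions:
      - '\b(?:urine\s+drug\s+screen|urine\s+tox\w*|uds)\b[^.\n]{0,60}\b(?:inconsistent|unexpected|abnormal|positive\s+for)\b'
    require_opioid_context: false
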