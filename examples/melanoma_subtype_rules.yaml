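# Example declarative subtype rule for `modbarcode barcode --rules`.
#
# Maps module ids of a melanoma-like module set to subtype labels under the
# unique-HI rule: a sample whose barcode has exactly one HI module among the
# listed ones gets that module's label; every other sample gets the fallback.
# For confident calls, pair this with a strict HI threshold (--z-hi 2.0).
modules:
  1: EMT-high
  2: Melanocytic
  3: ERK-high
fallback: Low
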