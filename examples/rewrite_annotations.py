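"""Rewrite MIRIAM URN annotations to identifiers.org URLs and back.

The two syntaxes name the same controlled-vocabulary entries; the
transforms are exact mutual inverses, so the final line reports zero
differences after a full round trip.
"""

from modelconv import convert_model_annotations, corpus, url_to_urn, urn_to_url

print(urn_to_url("urn:miriam:obo.chebi:CHEBI%3A36927"))
print(url_to_urn("http://identifiers.org/obo.chebi/CHEBI:36927"))

model = dict(corpus())["with_annotations"]
as_urls, report = convert_model_annotations(model, "urn_to_url")
print(f"converted {report.converted} resources, skipped {report.skipped}")
back, _ = convert_model_annotations(as_urls, "url_to_urn")
print("round trip restores annotations:", back.cv_terms == model.cv_terms)
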