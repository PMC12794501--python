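# Editable synonym map: free-text diagnosis -> canonical category.
# Entries extend the built-in spellings; lookup is case-insensitive and
# whitespace-normalized.  Which clinical entities collapse into which
# category is a study-level decision that belongs in this file.
situational syncope: REFLEX
carotid sinus syndrome: REFLEX
neurally mediated syncope: REFLEX
postural hypotension: ORTHOSTATIC_HYPOTENSION
drug-induced hypotension: ORTHOSTATIC_HYPOTENSION
arrhythmia: CARDIAC
atrial fibrillation: CARDIAC
bradyarrhythmia: CARDIAC
aortic stenosis: CARDIAC
myocardial ischemia: CARDIAC
functional tloc: PSYCHOGENIC_PSEUDOSYNCOPE
epileptic seizure: OTHER
hypoglycemia: OTHER
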