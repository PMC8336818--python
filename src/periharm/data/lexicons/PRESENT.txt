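current
currently
recent
recently
today
yesterday
now
tonight
last night
this morning
this week
monday
tuesday
wednesday
thursday
friday
saturday
sunday
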