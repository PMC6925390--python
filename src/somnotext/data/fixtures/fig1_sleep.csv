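subject_id,start,end
student,2015-10-05T00:00,2015-10-05T07:00
student,2015-10-06T00:00,2015-10-06T04:00
student,2015-10-06T13:30,2015-10-06T15:00
student,2015-10-07T03:00,2015-10-07T07:00
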