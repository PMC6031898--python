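token_id,category
meth_word_01,meth_word
meth_word_02,meth_word
meth_word_03,meth_word
meth_word_04,meth_word
meth_word_05,meth_word
meth_word_06,meth_word
meth_word_07,meth_word
meth_word_08,meth_word
neutral_word_01,neutral_word
neutral_word_02,neutral_word
neutral_word_03,neutral_word
neutral_word_04,neutral_word
neutral_word_05,neutral_word
neutral_word_06,neutral_word
neutral_word_07,neutral_word
neutral_word_08,neutral_word
meth_picture_01,meth_picture
meth_picture_02,meth_picture
meth_picture_03,meth_picture
meth_picture_04,meth_picture
meth_picture_05,meth_picture
meth_picture_06,meth_picture
meth_picture_07,meth_picture
meth_picture_08,meth_picture
neutral_picture_01,neutral_picture
neutral_picture_02,neutral_picture
neutral_picture_03,neutral_picture
neutral_picture_04,neutral_picture
neutral_picture_05,neutral_picture
neutral_picture_06,neutral_picture
neutral_picture_07,neutral_picture
neutral_picture_08,neutral_picture
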